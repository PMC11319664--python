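import numpy as np
import pytest
from sklearn.base import clone

from isingspikes import (
    IsingParameters,
    LearningConfig,
    MCConfig,
    MomentSet,
    PairwiseMaxEntIsing,
    exact_moments,
    fit_ising,
    goodness_of_fit,
    learning_rate,
    update_step,
)
from isingspikes.learning import DegenerateUnitError


def exact_config(**kwargs):
    defaults = dict(gradient_mode="exact", max_iterations=20000, tolerance=1e-8)
    defaults.update(kwargs)
    return LearningConfig(**defaults)


class TestLearningRate:
    def test_first_iteration_is_eta0(self):
        assert learning_rate(1, LearningConfig(eta0=0.1)) == pytest.approx(0.1)

    def test_power_law_decay(self):
        # 32^0.4 = 2^2 = 4 exactly
        cfg = LearningConfig(eta0=0.1, decay_exponent=0.4)
        assert learning_rate(32, cfg) == pytest.approx(0.025)

    def test_zero_exponent_is_constant(self):
        cfg = LearningConfig(eta0=0.07, decay_exponent=0.0)
        assert learning_rate(1000, cfg) == pytest.approx(0.07)

    def test_rejects_nonpositive_iteration(self):
        with pytest.raises(ValueError, match=">= 1"):
            learning_rate(0, LearningConfig())


class TestUpdateStep:
    def make(self, n=3):
        params = IsingParameters(np.zeros(n), np.zeros((n, n)))
        moments = MomentSet(
            means=np.full(n, -0.2),
            covariances=np.eye(n) * 0.5,
        )
        return params, moments

    def test_matched_moments_are_a_fixed_point(self):
        params, obs = self.make()
        out = update_step(params, obs, obs, 5, LearningConfig())
        np.testing.assert_array_equal(out.fields, params.fields)
        np.testing.assert_array_equal(out.couplings, params.couplings)

    def test_scalar_coupling_update(self):
        # J(n+1) = J(n) - eta * (C_mc - C_obs) = 0 - 0.1*0.2 = -0.02
        params, obs = self.make(2)
        model = MomentSet(
            means=obs.means.copy(),
            covariances=obs.covariances + np.array([[0, 0.2], [0.2, 0]]),
        )
        cfg = LearningConfig(eta0=0.1, decay_exponent=0.0)
        out = update_step(params, obs, model, 1, cfg)
        assert out.couplings[0, 1] == pytest.approx(-0.02)
        np.testing.assert_array_equal(out.fields, params.fields)

    def test_field_and_coupling_updates_decouple(self):
        params, obs = self.make(2)
        model = MomentSet(
            means=obs.means + 0.3, covariances=obs.covariances.copy()
        )
        out = update_step(params, obs, model, 1, LearningConfig(eta0=0.1))
        np.testing.assert_array_equal(out.couplings, params.couplings)
        np.testing.assert_allclose(out.fields, -0.03)


class TestFitExactGradients:
    def test_two_spin_closed_form_inversion(self):
        c = np.tanh(0.5)
        obs = MomentSet(
            means=np.zeros(2),
            covariances=np.array([[1.0, c], [c, 1.0]]),
            n_samples=1000,
        )
        params, trace = fit_ising(obs, exact_config())
        assert params.couplings[0, 1] == pytest.approx(0.5, abs=1e-3)
        assert np.all(np.abs(params.fields) < 1e-3)

    def test_independent_units_give_atanh_fields(self, rng):
        m = rng.uniform(-0.7, 0.4, 5)
        obs = MomentSet(
            means=m,
            covariances=np.diag(1 - m**2),
            n_samples=1000,
        )
        params, _ = fit_ising(obs, exact_config())
        offdiag = params.couplings[~np.eye(5, dtype=bool)]
        assert np.all(np.abs(offdiag) < 1e-3)
        np.testing.assert_allclose(params.fields, np.arctanh(m), atol=1e-3)

    def test_trace_monotonics(self):
        c = np.tanh(0.3)
        obs = MomentSet(
            means=np.zeros(2),
            covariances=np.array([[1.0, c], [c, 1.0]]),
            n_samples=100,
        )
        _, trace = fit_ising(obs, exact_config(max_iterations=500, tolerance=None))
        assert np.all(np.diff(trace.n) > 0)
        assert np.all(np.diff(trace.eta) < 0)
        # deterministic gradients with a decaying rate: mismatch shrinks
        burn = 10
        mm = trace.max_mismatch()[burn:]
        assert np.all(np.diff(mm) <= 1e-12)

    def test_degenerate_unit_raises_with_advice(self):
        obs = MomentSet(
            means=np.array([1.0, 0.0]),
            covariances=np.diag([0.0, 1.0]),
            n_samples=100,
        )
        with pytest.raises(DegenerateUnitError, match="clamp"):
            fit_ising(obs, exact_config())

    def test_degenerate_unit_clamped_on_request(self):
        obs = MomentSet(
            means=np.array([1.0, 0.0]),
            covariances=np.diag([0.0, 1.0]),
            n_samples=100,
        )
        with pytest.warns(UserWarning, match="clamping"):
            params, _ = fit_ising(
                obs, exact_config(max_iterations=2000), clamp_degenerate=True
            )
        assert np.isfinite(params.fields).all()


class TestGoodnessOfFit:
    def setup_model(self):
        rng = np.random.default_rng(21)
        j = np.triu(rng.normal(0, 0.25, (4, 4)), k=1)
        true = IsingParameters(rng.normal(-0.4, 0.3, 4), j + j.T)
        obs = exact_moments(true, 1.0)
        obs.n_samples = 10**6
        return true, obs

    def test_trained_model_sits_on_diagonal(self):
        true, obs = self.setup_model()
        params, _ = fit_ising(obs, exact_config())
        cfg = MCConfig(equilibration_sweeps=300, sample_sweeps=4000, seed=2)
        report = goodness_of_fit(params, obs, cfg, n_runs=8)
        assert np.all(
            np.abs(report.model_means - report.observed_means)
            < 3 * report.model_means_sd + 1e-9
        )
        assert np.all(
            np.abs(report.model_covariances - report.observed_covariances)
            < 3 * report.model_covariances_sd + 1e-9
        )

    def test_untrained_model_is_detected(self, rng):
        _, obs = self.setup_model()
        j = np.triu(rng.normal(0, 1.0, (4, 4)), k=1)
        bad = IsingParameters(rng.normal(1.5, 0.5, 4), j + j.T)
        cfg = MCConfig(equilibration_sweeps=300, sample_sweeps=4000, seed=3)
        report = goodness_of_fit(bad, obs, cfg, n_runs=8)
        worst = np.max(
            np.abs(report.model_means - report.observed_means)
            / (report.model_means_sd + 1e-12)
        )
        assert worst > 3

    def test_report_deterministic(self):
        true, obs = self.setup_model()
        cfg = MCConfig(equilibration_sweeps=100, sample_sweeps=1000, seed=5)
        a = goodness_of_fit(true, obs, cfg, n_runs=3)
        b = goodness_of_fit(true, obs, cfg, n_runs=3)
        np.testing.assert_array_equal(a.model_means, b.model_means)
        np.testing.assert_array_equal(a.model_covariances, b.model_covariances)


class TestEstimator:
    def make_raster(self, n_bins=3000):
        rng = np.random.default_rng(9)
        return np.where(rng.random((n_bins, 5)) < 0.25, 1, -1)

    def test_sklearn_protocol(self):
        est = PairwiseMaxEntIsing(max_iter=50)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        est.set_params(eta0=0.01)
        assert est.eta0 == 0.01

    def test_fit_sets_attributes(self):
        x = self.make_raster()
        est = PairwiseMaxEntIsing(
            gradient_mode="exact", max_iter=3000, tolerance=1e-5
        ).fit(x)
        assert est.n_features_in_ == 5
        assert est.fields_.shape == (5,)
        assert est.couplings_.shape == (5, 5)
        np.testing.assert_allclose(est.couplings_, est.couplings_.T)
        # independent data -> fields near atanh of the observed means,
        # up to leakage from the finite-sample covariances (~1/sqrt(M))
        m = x.astype(float).mean(axis=0)
        np.testing.assert_allclose(est.fields_, np.arctanh(m), atol=0.06)

    def test_zero_one_input_accepted(self):
        x01 = (self.make_raster(800) + 1) // 2
        est = PairwiseMaxEntIsing(
            gradient_mode="exact", max_iter=500, tolerance=1e-4
        ).fit(x01)
        assert np.isfinite(est.fields_).all()

    def test_sample_and_score(self):
        x = self.make_raster(1500)
        est = PairwiseMaxEntIsing(
            gradient_mode="exact", max_iter=2000, tolerance=1e-5
        ).fit(x)
        draws = est.sample(200, random_state=4)
        assert draws.shape == (200, 5)
        assert set(np.unique(draws)) <= {-1, 1}
        assert est.score(x) > -1e-3

    def test_unfitted_raises(self):
        with pytest.raises(AttributeError, match="not fitted"):
            PairwiseMaxEntIsing().sample(5)
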
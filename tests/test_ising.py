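import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from isingspikes import (
    IsingParameters,
    MCConfig,
    energy,
    exact_moments,
    mc_moments,
    metropolis_sample,
)
from isingspikes.ising import boltzmann_weights, enumerate_states


def pair_model(j, h=(0.0, 0.0)):
    return IsingParameters(
        fields=np.array(h), couplings=np.array([[0.0, j], [j, 0.0]])
    )


class TestParameters:
    def test_asymmetric_couplings_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            IsingParameters(
                fields=np.zeros(2), couplings=np.array([[0, 0.5], [0.2, 0]])
            )

    def test_nonzero_diagonal_rejected(self):
        with pytest.raises(ValueError, match="diagonal"):
            IsingParameters(fields=np.zeros(2), couplings=np.eye(2))

    def test_json_roundtrip(self, tmp_path, small_params):
        path = tmp_path / "params.json"
        small_params.to_json(path)
        back = IsingParameters.from_json(path)
        np.testing.assert_allclose(back.fields, small_params.fields)
        np.testing.assert_allclose(back.couplings, small_params.couplings)


class TestEnergy:
    def test_empty_hamiltonian(self):
        p = pair_model(0.0)
        assert energy(np.array([1.0, -1.0]), p) == 0.0

    def test_hand_example(self):
        p = pair_model(0.5, h=(1.0, -1.0))
        assert energy(np.array([1.0, 1.0]), p) == pytest.approx(-0.5)

    def test_dimension_mismatch(self, small_params):
        with pytest.raises(ValueError, match="does not match"):
            energy(np.ones(3), small_params)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**6 - 1), st.integers(0, 5), st.integers(0, 10**6))
    def test_single_flip_local_field_identity(self, code, site, seed):
        """Flipping spin k changes H by 2 s_k (h_k + sum_j J_kj s_j)."""
        n = 6
        site = site % n
        rng = np.random.default_rng(seed)
        j = np.triu(rng.normal(0, 0.5, (n, n)), k=1)
        params = IsingParameters(rng.normal(0, 1, n), j + j.T)
        s = enumerate_states(n)[code].copy()
        local = params.fields[site] + params.couplings[site] @ s
        predicted = 2.0 * s[site] * local
        s_flipped = s.copy()
        s_flipped[site] *= -1
        assert energy(s_flipped, params) - energy(s, params) == pytest.approx(
            predicted, abs=1e-8
        )


class TestExactMoments:
    def test_two_spin_closed_form(self):
        em = exact_moments(pair_model(0.5), 1.0)
        assert em.covariances[0, 1] == pytest.approx(np.tanh(0.5), abs=1e-12)
        assert em.covariances[0, 1] == pytest.approx(0.46211716, abs=1e-8)

    def test_independent_spins_factorize(self, rng):
        h = rng.normal(0, 1, 5)
        p = IsingParameters(h, np.zeros((5, 5)))
        for t in (0.7, 1.0, 2.0):
            em = exact_moments(p, t)
            np.testing.assert_allclose(em.means, np.tanh(h / t), atol=1e-12)
            offdiag = em.covariances[~np.eye(5, dtype=bool)]
            np.testing.assert_allclose(offdiag, 0, atol=1e-12)

    def test_zero_field_spin_flip_symmetry(self, rng):
        j = np.triu(rng.normal(0, 0.6, (6, 6)), k=1)
        p = IsingParameters(np.zeros(6), j + j.T)
        em = exact_moments(p, 1.0)
        assert np.all(np.abs(em.means) < 1e-12)

    def test_refuses_large_systems(self):
        p = IsingParameters(np.zeros(21), np.zeros((21, 21)))
        with pytest.raises(ValueError, match="N <= 20"):
            exact_moments(p, 1.0)

    def test_triplets_match_direct_weighted_sum(self, small_params):
        em = exact_moments(small_params, 1.0, include_triplets=True)
        states = enumerate_states(4)
        w = boltzmann_weights(small_params, 1.0, states)
        xc = states - w @ states
        expected = []
        for i in range(4):
            for j in range(i + 1, 4):
                for k in range(j + 1, 4):
                    expected.append(np.sum(w * xc[:, i] * xc[:, j] * xc[:, k]))
        np.testing.assert_allclose(em.triplets, expected, atol=1e-12)


class TestMetropolis:
    def test_deterministic_per_seed(self, small_params):
        cfg = MCConfig(equilibration_sweeps=10, sample_sweeps=50, seed=3)
        a = metropolis_sample(small_params, 1.0, cfg)
        b = metropolis_sample(small_params, 1.0, cfg)
        assert np.array_equal(a, b)

    def test_infinite_temperature_is_fair_coin(self, small_params):
        cfg = MCConfig(equilibration_sweeps=100, sample_sweeps=4000, seed=2)
        samples = metropolis_sample(small_params, 1e6, cfg)
        assert np.all(np.abs(samples.mean(axis=0)) < 3 / np.sqrt(len(samples)))

    def test_two_spin_correlation(self):
        cfg = MCConfig(equilibration_sweeps=500, sample_sweeps=20000, seed=4)
        mom = mc_moments(pair_model(0.5), 1.0, cfg)
        resid = abs(mom.covariances[0, 1] - np.tanh(0.5))
        assert resid < 3 * mom.cov_se[0, 1]

    def test_temperature_must_be_positive(self, small_params):
        cfg = MCConfig(seed=1)
        with pytest.raises(ValueError, match="temperature"):
            metropolis_sample(small_params, 0.0, cfg)

    def test_glauber_agrees_with_metropolis(self):
        p = pair_model(0.5)
        cfg = MCConfig(
            equilibration_sweeps=500, sample_sweeps=20000, seed=8, rule="glauber"
        )
        mom = mc_moments(p, 1.0, cfg)
        assert abs(mom.covariances[0, 1] - np.tanh(0.5)) < 4 * mom.cov_se[0, 1]

    def test_sequential_update_order(self):
        p = pair_model(0.5)
        cfg = MCConfig(
            equilibration_sweeps=500,
            sample_sweeps=20000,
            seed=9,
            update_order="sequential",
        )
        mom = mc_moments(p, 1.0, cfg)
        assert abs(mom.covariances[0, 1] - np.tanh(0.5)) < 4 * mom.cov_se[0, 1]


class TestMCAgainstEnumeration:
    def test_strong_field_saturation(self):
        p = IsingParameters(np.full(3, 10.0), np.zeros((3, 3)))
        cfg = MCConfig(equilibration_sweeps=100, sample_sweeps=2000, seed=6)
        mom = mc_moments(p, 1.0, cfg)
        assert np.all(mom.means > 0.99)

    def test_independent_spins_tanh(self, rng):
        h = rng.normal(-0.5, 0.5, 4)
        p = IsingParameters(h, np.zeros((4, 4)))
        cfg = MCConfig(equilibration_sweeps=500, sample_sweeps=20000, seed=7)
        mom = mc_moments(p, 1.3, cfg)
        np.testing.assert_array_less(
            np.abs(mom.means - np.tanh(h / 1.3)), 3 * mom.mean_se + 1e-9
        )

    def test_error_shrinks_with_sample_size(self, small_params):
        """Quadrupling the sample count roughly halves the moment error."""
        exact = exact_moments(small_params, 1.0)

        def rms_error(sweeps, seed):
            cfg = MCConfig(
                equilibration_sweeps=500, sample_sweeps=sweeps, seed=seed
            )
            mom = mc_moments(small_params, 1.0, cfg)
            return np.sqrt(
                np.mean((mom.means - exact.means) ** 2)
                + np.mean((mom.covariances - exact.covariances) ** 2)
            )

        # average over independent repeats to beat the noise on the ratio
        small = np.mean([rms_error(2000, s) for s in range(10)])
        large = np.mean([rms_error(32000, s + 100) for s in range(10)])
        assert large < 0.5 * small
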
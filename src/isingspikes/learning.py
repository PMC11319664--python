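"""Inverse Ising inference by Boltzmann-machine moment matching.

Given observed means ``<s_i>^obs`` and covariances ``C_ij^obs``, the
maximum-entropy model with those constraints is the pairwise Ising model;
its parameters are found by the iterative scheme

    J_ij(n+1) = J_ij(n) - eta(n) [C_ij^MC   - C_ij^obs]
    h_i (n+1) = h_i (n) - eta(n) [<s_i>^MC  - <s_i>^obs]

run at the operating temperature ``T_o`` (1 by convention), starting from
``h = 0``, ``J = 0`` at ``n = 1``, with a learning rate decaying like
``eta(n) = eta0 / n^0.4``.  Model moments per iteration come either from
a warm-started Metropolis chain (``gradient_mode="monte_carlo"``) or from
exact enumeration for small systems (``gradient_mode="exact"``).

:class:`PairwiseMaxEntIsing` wraps the procedure as a scikit-learn style
estimator over raw rasters (rows = time bins, columns = units); the
module-level functions expose the individual steps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dataclass_field

import numpy as np
from sklearn.base import BaseEstimator

from .ising import (
    IsingParameters,
    MCConfig,
    boltzmann_weights,
    enumerate_states,
    exact_moments,
    metropolis_sample,
    mc_moments,
    moments_from_samples,
)
from .moments import MomentSet

__all__ = [
    "LearningConfig",
    "LearningTrace",
    "DegenerateUnitError",
    "learning_rate",
    "update_step",
    "fit_ising",
    "goodness_of_fit",
    "GoodnessOfFit",
    "PairwiseMaxEntIsing",
]


class DegenerateUnitError(ValueError):
    """A unit with |<s_i>| = 1 makes its field diverge under moment matching."""


@dataclass
class LearningConfig:
    """Hyper-parameters of the moment-matching iteration.

    ``eta0`` scales the learning rate (``eta(n) = eta0 * n^-decay_exponent``);
    the default 0.05 is stable for +/-1 moment scales up to N=60.
    ``tolerance``, when set, stops early once the max moment mismatch of an
    iteration falls below it; otherwise the full ``max_iterations`` budget
    (80,000 by default) is spent.  ``mc`` configures the per-iteration
    chain for ``gradient_mode="monte_carlo"``.
    """

    eta0: float = 0.05
    decay_exponent: float = 0.4
    max_iterations: int = 80000
    mc: MCConfig = dataclass_field(
        default_factory=lambda: MCConfig(
            equilibration_sweeps=100, sample_sweeps=1000, thinning=1, seed=0
        )
    )
    tolerance: float | None = None
    gradient_mode: str = "monte_carlo"

    def __post_init__(self):
        if self.eta0 <= 0:
            raise ValueError("eta0 must be > 0")
        if self.decay_exponent < 0:
            raise ValueError("decay_exponent must be >= 0")
        if self.max_iterations < 1:
            raise ValueError("max_iterations must be >= 1")
        if self.gradient_mode not in ("monte_carlo", "exact"):
            raise ValueError(f"unknown gradient_mode {self.gradient_mode!r}")


@dataclass
class LearningTrace:
    """Per-iteration diagnostics of the fit."""

    n: np.ndarray
    eta: np.ndarray
    max_cov_mismatch: np.ndarray
    max_mean_mismatch: np.ndarray
    mean_squared_mismatch: np.ndarray
    converged: bool = False

    def max_mismatch(self) -> np.ndarray:
        return np.maximum(self.max_cov_mismatch, self.max_mean_mismatch)


def learning_rate(n: int, config: LearningConfig) -> float:
    """eta(n) = eta0 * n^{-decay_exponent} for iteration n >= 1."""
    if n < 1:
        raise ValueError(f"iteration index must be >= 1, got {n}")
    return config.eta0 * float(n) ** (-config.decay_exponent)


def update_step(
    params: IsingParameters,
    observed: MomentSet,
    model: MomentSet,
    n: int,
    config: LearningConfig,
) -> IsingParameters:
    """One elementwise moment-matching update of h and J."""
    n_units = params.n_units
    if observed.n_units != n_units or model.n_units != n_units:
        raise ValueError("observed/model moment dimensions do not match parameters")
    eta = learning_rate(n, config)
    h = params.fields - eta * (model.means - observed.means)
    j = params.couplings - eta * (model.covariances - observed.covariances)
    j = (j + j.T) / 2.0
    np.fill_diagonal(j, 0.0)
    return IsingParameters(h, j, params.reference_temperature)


def _check_degenerate(means: np.ndarray, n_samples: int, clamp: bool) -> np.ndarray:
    sat = np.abs(means) >= 1.0
    if not sat.any():
        return means
    if not clamp:
        idx = np.flatnonzero(sat)
        raise DegenerateUnitError(
            f"units {idx.tolist()} have |<s_i>| = 1 (never/always firing); "
            "their fields diverge — clamp them (clamp_degenerate=True) or "
            "drop the units before fitting"
        )
    limit = 1.0 - 1.0 / max(n_samples, 2)
    warnings.warn(
        f"clamping {int(sat.sum())} degenerate unit mean(s) to +/-{limit:.6g}",
        stacklevel=3,
    )
    return np.clip(means, -limit, limit)


def fit_ising(
    observed: MomentSet,
    config: LearningConfig | None = None,
    operating_temperature: float = 1.0,
    clamp_degenerate: bool = False,
    record_every: int = 1,
) -> tuple[IsingParameters, LearningTrace]:
    """Run the full moment-matching loop against observed moments.

    Starts from ``h = 0``, ``J = 0``.  Monte Carlo gradients warm-start
    each iteration's chain from the previous iteration's last retained
    configuration, with a fresh per-iteration seed derived from
    ``config.mc.seed``; the whole fit is deterministic for fixed seeds.
    """
    config = config or LearningConfig()
    n_units = observed.n_units
    target_means = _check_degenerate(
        observed.means, observed.n_samples, clamp_degenerate
    )
    target = MomentSet(
        means=target_means,
        covariances=observed.covariances,
        source=observed.source,
        n_samples=observed.n_samples,
    )

    params = IsingParameters(
        np.zeros(n_units), np.zeros((n_units, n_units)), operating_temperature
    )
    exact = config.gradient_mode == "exact"
    states = enumerate_states(n_units) if exact else None
    warm_state: np.ndarray | None = None
    offdiag = ~np.eye(n_units, dtype=bool)

    rec_n, rec_eta, rec_dc, rec_dm, rec_mse = [], [], [], [], []
    converged = False
    for n in range(1, config.max_iterations + 1):
        if exact:
            w = boltzmann_weights(params, operating_temperature, states)
            m = w @ states
            c = states.T @ (states * w[:, None]) - np.outer(m, m)
            model = MomentSet(means=m, covariances=(c + c.T) / 2.0, source="model")
        else:
            it_cfg = MCConfig(
                equilibration_sweeps=config.mc.equilibration_sweeps,
                sample_sweeps=config.mc.sample_sweeps,
                thinning=config.mc.thinning,
                seed=int((config.mc.seed + n) % 2**31),
                update_order=config.mc.update_order,
                rule=config.mc.rule,
            )
            samples = metropolis_sample(
                params, operating_temperature, it_cfg, initial_state=warm_state
            )
            warm_state = samples[-1].astype(float)
            model = moments_from_samples(samples, n_blocks=1)

        dm = model.means - target.means
        dc = model.covariances - target.covariances
        max_dm = float(np.abs(dm).max())
        max_dc = float(np.abs(dc[offdiag]).max()) if n_units > 1 else 0.0
        if n % record_every == 0 or n == 1:
            rec_n.append(n)
            rec_eta.append(learning_rate(n, config))
            rec_dc.append(max_dc)
            rec_dm.append(max_dm)
            rec_mse.append(
                float((dm**2).sum() + (dc[offdiag] ** 2).sum() / 2.0)
                / (n_units + n_units * (n_units - 1) // 2)
            )
        if config.tolerance is not None and max(max_dm, max_dc) < config.tolerance:
            converged = True
            break
        params = update_step(params, target, model, n, config)

    trace = LearningTrace(
        n=np.array(rec_n),
        eta=np.array(rec_eta),
        max_cov_mismatch=np.array(rec_dc),
        max_mean_mismatch=np.array(rec_dm),
        mean_squared_mismatch=np.array(rec_mse),
        converged=converged,
    )
    return params, trace


@dataclass
class GoodnessOfFit:
    """Paired observed/model moments with model-side spread across runs."""

    observed_means: np.ndarray
    model_means: np.ndarray
    model_means_sd: np.ndarray
    observed_covariances: np.ndarray  # off-diagonal, i<j order
    model_covariances: np.ndarray
    model_covariances_sd: np.ndarray
    max_abs_mean_deviation: float
    mean_abs_mean_deviation: float
    max_abs_cov_deviation: float
    mean_abs_cov_deviation: float
    n_runs: int


def goodness_of_fit(
    params: IsingParameters,
    observed: MomentSet,
    config: MCConfig,
    n_runs: int = 10,
    temperature: float | None = None,
) -> GoodnessOfFit:
    """Compare model moments with the observed ones, Fig.-on-the-diagonal style.

    The model side is averaged over ``n_runs`` independent Metropolis
    runs (seeds derived from ``config.seed``); the per-run spread gives
    the model-side standard deviations used as error bars.
    """
    temperature = (
        params.reference_temperature if temperature is None else temperature
    )
    n = params.n_units
    iu = np.triu_indices(n, k=1)
    run_means = np.empty((n_runs, n))
    run_covs = np.empty((n_runs, iu[0].size))
    for r in range(n_runs):
        cfg = MCConfig(
            equilibration_sweeps=config.equilibration_sweeps,
            sample_sweeps=config.sample_sweeps,
            thinning=config.thinning,
            seed=int((config.seed + 7919 * (r + 1)) % 2**31),
            update_order=config.update_order,
            rule=config.rule,
        )
        mom = mc_moments(params, temperature, cfg, n_blocks=1)
        run_means[r] = mom.means
        run_covs[r] = mom.covariances[iu]
    model_means = run_means.mean(axis=0)
    model_covs = run_covs.mean(axis=0)
    dev_m = np.abs(model_means - observed.means)
    dev_c = np.abs(model_covs - observed.covariances[iu])
    return GoodnessOfFit(
        observed_means=observed.means.copy(),
        model_means=model_means,
        model_means_sd=run_means.std(axis=0, ddof=1),
        observed_covariances=observed.covariances[iu].copy(),
        model_covariances=model_covs,
        model_covariances_sd=run_covs.std(axis=0, ddof=1),
        max_abs_mean_deviation=float(dev_m.max()),
        mean_abs_mean_deviation=float(dev_m.mean()),
        max_abs_cov_deviation=float(dev_c.max()),
        mean_abs_cov_deviation=float(dev_c.mean()),
        n_runs=n_runs,
    )


class PairwiseMaxEntIsing(BaseEstimator):
    """Pairwise maximum-entropy (inverse Ising) model of binary activity.

    Fits local fields and symmetric couplings so that the Boltzmann
    distribution at the operating temperature reproduces the sample's
    unit means and pairwise covariances.  Follows the scikit-learn
    estimator protocol: ``X`` has one row per time bin and one column
    per unit, with entries in {-1, +1} (or {0, 1}, mapped 0 -> -1).

    Parameters
    ----------
    eta0, decay_exponent, max_iter, tolerance
        Learning-rate schedule ``eta0 / n^decay_exponent`` and stopping
        rule of the moment-matching loop.
    gradient_mode
        "monte_carlo" (warm-started Metropolis gradients, any N) or
        "exact" (enumeration gradients, N <= 20).
    operating_temperature
        Temperature ``T_o`` the model is inferred at (default 1).
    equilibration_sweeps, sample_sweeps, thinning
        Per-iteration Monte Carlo budget (monte_carlo mode only).
    clamp_degenerate
        Clamp |<s_i>| = 1 units to 1 - 1/M instead of raising.
    random_state
        Base seed for every chain used during fitting.

    Attributes
    ----------
    fields_ : ndarray of shape (n_units,)
        Inferred local fields h_i.
    couplings_ : ndarray of shape (n_units, n_units)
        Inferred symmetric couplings J_ij, zero diagonal.
    trace_ : LearningTrace
        Per-iteration mismatch diagnostics.
    observed_moments_ : MomentSet
        The empirical moments the model was matched to.
    """

    def __init__(
        self,
        eta0: float = 0.05,
        decay_exponent: float = 0.4,
        max_iter: int = 80000,
        tolerance: float | None = None,
        gradient_mode: str = "monte_carlo",
        operating_temperature: float = 1.0,
        equilibration_sweeps: int = 100,
        sample_sweeps: int = 1000,
        thinning: int = 1,
        clamp_degenerate: bool = True,
        random_state: int = 0,
    ):
        self.eta0 = eta0
        self.decay_exponent = decay_exponent
        self.max_iter = max_iter
        self.tolerance = tolerance
        self.gradient_mode = gradient_mode
        self.operating_temperature = operating_temperature
        self.equilibration_sweeps = equilibration_sweeps
        self.sample_sweeps = sample_sweeps
        self.thinning = thinning
        self.clamp_degenerate = clamp_degenerate
        self.random_state = random_state

    def _validate_spins(self, X) -> np.ndarray:
        x = np.asarray(X)
        if x.ndim != 2:
            raise ValueError("X must be 2-D (n_bins, n_units)")
        uniq = set(np.unique(x).tolist())
        if uniq <= {0, 1} and 0 in uniq:
            x = 2 * x - 1
        elif not uniq <= {-1, 1}:
            raise ValueError("X entries must be -1/+1 or 0/1")
        return x.astype(np.int8)

    def _learning_config(self) -> LearningConfig:
        return LearningConfig(
            eta0=self.eta0,
            decay_exponent=self.decay_exponent,
            max_iterations=self.max_iter,
            mc=MCConfig(
                equilibration_sweeps=self.equilibration_sweeps,
                sample_sweeps=self.sample_sweeps,
                thinning=self.thinning,
                seed=self.random_state,
            ),
            tolerance=self.tolerance,
            gradient_mode=self.gradient_mode,
        )

    def fit(self, X, y=None):
        """Infer fields and couplings from a raster of spin states."""
        x = self._validate_spins(X)
        n_bins, n_units = x.shape
        if n_units < 2:
            raise ValueError("need at least 2 units")
        xf = x.astype(float)
        m = xf.mean(axis=0)
        c = xf.T @ xf / n_bins - np.outer(m, m)
        observed = MomentSet(
            means=m, covariances=(c + c.T) / 2.0, source="observed", n_samples=n_bins
        )
        params, trace = fit_ising(
            observed,
            self._learning_config(),
            operating_temperature=self.operating_temperature,
            clamp_degenerate=self.clamp_degenerate,
        )
        self.n_features_in_ = n_units
        self.fields_ = params.fields
        self.couplings_ = params.couplings
        self.params_ = params
        self.trace_ = trace
        self.observed_moments_ = observed
        return self

    def predict_moments(
        self,
        method: str = "auto",
        include_triplets: bool = False,
        mc_config: MCConfig | None = None,
        temperature: float | None = None,
    ) -> MomentSet:
        """Model moments of the fitted distribution (exact or Monte Carlo)."""
        self._check_fitted()
        t = self.operating_temperature if temperature is None else temperature
        if method == "auto":
            method = "exact" if self.n_features_in_ <= 20 else "monte_carlo"
        if method == "exact":
            return exact_moments(self.params_, t, include_triplets)
        cfg = mc_config or MCConfig(
            equilibration_sweeps=1000,
            sample_sweeps=100000,
            thinning=1,
            seed=self.random_state,
        )
        return mc_moments(self.params_, t, cfg, include_triplets)

    def sample(
        self,
        n_samples: int,
        temperature: float | None = None,
        random_state: int | None = None,
        thinning: int = 5,
    ) -> np.ndarray:
        """Draw configurations from the fitted model, rows = time bins."""
        self._check_fitted()
        t = self.operating_temperature if temperature is None else temperature
        cfg = MCConfig(
            equilibration_sweeps=1000,
            sample_sweeps=n_samples * thinning,
            thinning=thinning,
            seed=self.random_state if random_state is None else random_state,
        )
        return metropolis_sample(self.params_, t, cfg)

    def score(self, X, y=None) -> float:
        """Negative mean squared moment mismatch against a raster."""
        self._check_fitted()
        x = self._validate_spins(X).astype(float)
        m = x.mean(axis=0)
        c = x.T @ x / x.shape[0] - np.outer(m, m)
        model = self.predict_moments()
        iu = np.triu_indices(self.n_features_in_, k=1)
        mse = np.concatenate(
            [(model.means - m), (model.covariances - c)[iu]]
        )
        return -float(np.mean(mse**2))

    def _check_fitted(self):
        if not hasattr(self, "params_"):
            raise AttributeError(
                "this PairwiseMaxEntIsing instance is not fitted yet"
            )
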
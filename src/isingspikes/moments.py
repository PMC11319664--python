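"""Time-averaged statistics of spike rasters.

All moments follow the population (1/M) normalization of the
maximum-entropy constraints: mean activity ``<s_i> = (1/M) sum_t s_i(t)``,
connected pairwise correlation ``C_ij = <s_i s_j> - <s_i><s_j>``, and the
connected third central moment
``T_ijk = (1/M) sum_t (s_i - <s_i>)(s_j - <s_j>)(s_k - <s_k>)``
over distinct triples ``i < j < k``.

The simultaneous-spike count ``K(t)`` (number of units in the +1 state in
bin ``t``) yields the distribution ``P(K)``, which for sparse cultures is
well described by a decaying exponential ``p(K) = alpha * exp(-beta K)``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from ._kernels import centered_triplet_means
from .raster import SpikeRaster

__all__ = [
    "MomentSet",
    "SpikeCountDistribution",
    "triplet_indices",
    "mean_activity",
    "covariance",
    "triplet_correlation",
    "observed_moments",
    "simultaneous_spike_distribution",
    "fit_exponential",
]


def triplet_indices(n_units: int) -> np.ndarray:
    """Index triples (i, j, k), i<j<k, in the order triplet arrays use."""
    return np.array(list(itertools.combinations(range(n_units), 3)), dtype=np.int64)


@dataclass
class MomentSet:
    """First, second (connected) and optional third (connected) moments.

    ``source`` tags provenance ("observed" for data, "model" for Monte
    Carlo or enumeration averages); ``n_samples`` is the number of
    configurations the estimates were taken over.  Standard errors are
    populated only for Monte Carlo estimates.
    """

    means: np.ndarray
    covariances: np.ndarray
    triplets: np.ndarray | None = None
    source: str = "observed"
    n_samples: int = 0
    mean_se: np.ndarray | None = None
    cov_se: np.ndarray | None = None
    triplet_se: np.ndarray | None = None

    def __post_init__(self):
        self.means = np.asarray(self.means, dtype=float)
        self.covariances = np.asarray(self.covariances, dtype=float)
        n = self.means.shape[0]
        if self.covariances.shape != (n, n):
            raise ValueError("covariance shape does not match means")
        if not np.allclose(self.covariances, self.covariances.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        if self.triplets is not None:
            self.triplets = np.asarray(self.triplets, dtype=float)

    @property
    def n_units(self) -> int:
        return self.means.shape[0]

    def offdiag_covariances(self) -> np.ndarray:
        """Upper-triangle (i<j) covariances as a flat vector."""
        iu = np.triu_indices(self.n_units, k=1)
        return self.covariances[iu]


@dataclass
class SpikeCountDistribution:
    """Empirical distribution of the simultaneous-spike count K.

    ``k_samples`` keeps the per-bin counts so that a goodness-of-fit test
    can operate on the underlying sample rather than the histogram.
    Fit fields stay ``None`` until :func:`fit_exponential` is applied.
    """

    k_values: np.ndarray
    probabilities: np.ndarray
    k_samples: np.ndarray = field(repr=False, default=None)
    fit_alpha: float | None = None
    fit_beta: float | None = None
    ks_statistic: float | None = None
    ks_pvalue: float | None = None


def mean_activity(raster: SpikeRaster) -> np.ndarray:
    """Per-unit time-averaged activity ``<s_i>``, in [-1, 1]."""
    return raster.states.mean(axis=1)


def covariance(raster: SpikeRaster) -> np.ndarray:
    """Connected pairwise correlations ``C_ij`` (1/M normalization).

    The diagonal is the per-unit variance ``1 - <s_i>^2`` of a +/-1
    variable.
    """
    if raster.n_bins < 2:
        raise ValueError("need at least 2 time bins to estimate covariances")
    x = raster.states.astype(float)
    m = x.mean(axis=1)
    c = x @ x.T / raster.n_bins - np.outer(m, m)
    return (c + c.T) / 2.0


def triplet_correlation(raster: SpikeRaster) -> np.ndarray:
    """Connected three-point correlations ``T_ijk`` for all i<j<k."""
    if raster.n_units < 3:
        raise ValueError("need at least 3 units for triplet correlations")
    x = raster.states.T.astype(np.float64)
    xc = x - x.mean(axis=0)
    return centered_triplet_means(np.ascontiguousarray(xc))


def observed_moments(raster: SpikeRaster, include_triplets: bool = False) -> MomentSet:
    """Bundle the observed moments the inverse problem consumes."""
    return MomentSet(
        means=mean_activity(raster),
        covariances=covariance(raster),
        triplets=triplet_correlation(raster) if include_triplets else None,
        source="observed",
        n_samples=raster.n_bins,
    )


def simultaneous_spike_distribution(raster: SpikeRaster) -> SpikeCountDistribution:
    """Empirical P(K): probability that K units fire in the same bin."""
    k_samples = (raster.states == 1).sum(axis=0)
    counts = np.bincount(k_samples, minlength=raster.n_units + 1)
    return SpikeCountDistribution(
        k_values=np.arange(raster.n_units + 1),
        probabilities=counts / raster.n_bins,
        k_samples=k_samples,
    )


def _exp_model(k, alpha, beta):
    return alpha * np.exp(-beta * k)


def _least_squares_exp(k, p, scale):
    """Fit p(K) = alpha exp(-beta K); returns (alpha, beta)."""
    # log-linear start (and result, for scale="log")
    slope, intercept = np.polyfit(k, np.log(p), 1)
    alpha0, beta0 = float(np.exp(intercept)), float(-slope)
    if scale == "log":
        return alpha0, beta0
    popt, _ = optimize.curve_fit(
        _exp_model, k, p, p0=(max(alpha0, 1e-12), beta0), maxfev=20000
    )
    return float(popt[0]), float(popt[1])


def _ks_discrete(k_samples, pmf):
    """Two-sided KS distance between sample ECDF and a discrete model CDF."""
    n_support = pmf.shape[0]
    counts = np.bincount(k_samples, minlength=n_support)
    ecdf = np.cumsum(counts) / k_samples.size
    mcdf = np.cumsum(pmf)
    return float(np.max(np.abs(ecdf - mcdf)))


def fit_exponential(
    dist: SpikeCountDistribution,
    scale: str = "linear",
    bootstrap: int = 1000,
    seed: int = 0,
) -> SpikeCountDistribution:
    """Least-squares exponential fit of P(K) with a seeded KS test.

    ``(alpha, beta)`` minimize ``sum_K (P(K) - alpha e^{-beta K})^2`` over
    the bins with ``P(K) > 0`` (``scale="log"`` switches to a log-linear
    fit).  The KS statistic compares the per-bin K samples with the fitted
    exponential normalized over the observed support; because the
    parameters are estimated from the same sample and K is discrete, the
    p-value comes from a parametric bootstrap in which each replicate is
    drawn from the fitted model and re-fitted before its KS distance is
    taken.
    """
    mask = dist.probabilities > 0
    k = dist.k_values[mask].astype(float)
    p = dist.probabilities[mask]
    if k.size < 3:
        raise ValueError(
            f"exponential fit needs >= 3 populated K bins, got {k.size}"
        )
    if scale not in ("linear", "log"):
        raise ValueError(f"unknown fit scale {scale!r}")
    alpha, beta = _least_squares_exp(k, p, scale)

    out = replace(dist, fit_alpha=alpha, fit_beta=beta)
    if dist.k_samples is None or bootstrap <= 0:
        return out

    support = dist.k_values.astype(float)
    pmf = _exp_model(support, alpha, beta)
    pmf = pmf / pmf.sum()
    d_obs = _ks_discrete(dist.k_samples, pmf)

    rng = np.random.default_rng(seed)
    n = dist.k_samples.size
    exceed = 0
    for _ in range(bootstrap):
        sample = rng.choice(support.astype(int), size=n, p=pmf)
        counts = np.bincount(sample, minlength=support.size)
        probs = counts / n
        bmask = probs > 0
        if bmask.sum() < 3:
            continue
        try:
            a_b, b_b = _least_squares_exp(
                support[bmask], probs[bmask], scale
            )
        except RuntimeError:
            continue
        pmf_b = _exp_model(support, a_b, b_b)
        pmf_b = pmf_b / pmf_b.sum()
        if _ks_discrete(sample, pmf_b) >= d_obs:
            exceed += 1
    out.ks_statistic = d_obs
    out.ks_pvalue = (1 + exceed) / (1 + bootstrap)
    return out
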
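"""Generalization diagnostics for a fitted pairwise model.

Covers the characterization of learned parameter distributions (fields
are typically left-skewed, couplings near-Gaussian around zero), the
three-point-correlation prediction test — the model is fitted to means
and pairwise covariances only, so agreement of its triplet correlations
with the observed ones is genuine generalization — the mean relative
triplet error, and equal-count binning of paired triplet values for
display with per-bin dispersions.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .ising import IsingParameters
from .moments import MomentSet

__all__ = [
    "DistributionSummary",
    "BinnedTriplets",
    "summarize_parameters",
    "triplet_prediction_error",
    "bin_triplets",
]


@dataclass
class DistributionSummary:
    """Location/shape summary of a parameter sample, optional Gaussian fit."""

    values: np.ndarray
    mean: float
    std: float
    skewness: float
    gaussian_mu: float | None = None
    gaussian_sigma: float | None = None
    ks_statistic: float | None = None
    ks_pvalue: float | None = None


def _summarize(values: np.ndarray, fit_gaussian: bool) -> DistributionSummary:
    values = np.asarray(values, dtype=float)
    out = DistributionSummary(
        values=values,
        mean=float(values.mean()),
        std=float(values.std(ddof=1)) if values.size > 1 else 0.0,
        skewness=float(stats.skew(values)),
    )
    if fit_gaussian:
        mu, sigma = stats.norm.fit(values)
        d, p = stats.kstest(values, "norm", args=(mu, sigma))
        out.gaussian_mu = float(mu)
        out.gaussian_sigma = float(sigma)
        out.ks_statistic = float(d)
        out.ks_pvalue = float(p)
    return out


def summarize_parameters(
    params: IsingParameters, fit_gaussian: bool = True
) -> tuple[DistributionSummary, DistributionSummary]:
    """Distribution summaries of the fields h_i and couplings J_ij (i<j).

    The Gaussian fit (maximum likelihood) with a KS test is applied to
    the couplings — learned couplings are typically well described by a
    zero-centered Gaussian — and, when requested, to the fields too,
    whose summary is mainly read for its (negative) skewness.
    """
    iu = np.triu_indices(params.n_units, k=1)
    h_summary = _summarize(params.fields, fit_gaussian)
    j_summary = _summarize(params.couplings[iu], fit_gaussian)
    return h_summary, j_summary


def triplet_prediction_error(
    model: MomentSet,
    observed: MomentSet,
    epsilon: float = 1e-3,
) -> tuple[float, int]:
    """Mean relative triplet error  <(T^model - T^obs) / T^obs>.

    Averaged over triples with ``|T^obs| >= epsilon``; the statistic is
    ill-defined at vanishing observed triplets, so the guard excludes
    them and the number excluded is returned alongside.
    """
    if model.triplets is None or observed.triplets is None:
        raise ValueError("both MomentSets must carry triplet correlations")
    t_m = np.asarray(model.triplets, dtype=float)
    t_o = np.asarray(observed.triplets, dtype=float)
    if t_m.shape != t_o.shape:
        raise ValueError("triplet arrays must cover identical index triples")
    keep = np.abs(t_o) >= epsilon
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError(
            f"all {t_o.size} triples fall below the guard epsilon={epsilon}; "
            "relative error undefined"
        )
    rel = (t_m[keep] - t_o[keep]) / t_o[keep]
    return float(rel.mean()), n_excluded


@dataclass
class BinnedTriplets:
    """Equal-count bins of paired (observed, model) triplet values."""

    observed_mean: np.ndarray
    model_mean: np.ndarray
    model_std: np.ndarray
    counts: np.ndarray
    n_bins: int


def bin_triplets(
    model_triplets: np.ndarray,
    observed_triplets: np.ndarray,
    n_bins: int = 100,
) -> BinnedTriplets:
    """Quantile-bin paired triplets by observed value (bins never empty).

    Triples are sorted by the observed value and split into ``n_bins``
    contiguous groups whose populations differ by at most one.  Per bin:
    mean observed value, mean model value, and the standard deviation of
    the model values (the displayed error bar).  If there are fewer
    triples than bins, the bin count is reduced with a warning.
    """
    t_m = np.asarray(model_triplets, dtype=float)
    t_o = np.asarray(observed_triplets, dtype=float)
    if t_m.shape != t_o.shape or t_m.ndim != 1:
        raise ValueError("triplet arrays must be 1-D and of equal length")
    if t_o.size < n_bins:
        warnings.warn(
            f"only {t_o.size} triples for {n_bins} bins; using {t_o.size} bins",
            stacklevel=2,
        )
        n_bins = t_o.size
    order = np.argsort(t_o, kind="stable")
    groups = np.array_split(order, n_bins)
    obs_mean = np.array([t_o[g].mean() for g in groups])
    mod_mean = np.array([t_m[g].mean() for g in groups])
    mod_std = np.array(
        [t_m[g].std(ddof=1) if g.size > 1 else 0.0 for g in groups]
    )
    counts = np.array([g.size for g in groups])
    return BinnedTriplets(
        observed_mean=obs_mean,
        model_mean=mod_mean,
        model_std=mod_std,
        counts=counts,
        n_bins=n_bins,
    )
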
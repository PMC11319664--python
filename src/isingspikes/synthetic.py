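"""Synthetic spike rasters with the statistical structure of culture data.

Real multielectrode recordings of cortical cultures are sparse
(predominantly -1), their simultaneous-spike counts decay roughly
exponentially, and inferred pairwise models show near-Gaussian couplings
centered at zero with mostly negative, left-skewed fields.  The
generators here produce data with those features from two forward
models:

* a ground-truth Ising model with Gaussian couplings and left-skewed
  fields, sampled by Metropolis Monte Carlo (parameter-recovery surface);
* independent Bernoulli units (the uncorrelated null).

Defaults mirror a 60-electrode, 20,000-bin recording.  The default
coupling scale ``j_sigma = 1.2/sqrt(N)`` keeps the model free of
spontaneous order at the operating temperature T=1 (the random field
dominates) while placing its thermodynamic crossover — the peak of the
specific heat — above T=1, mirroring inferred culture models; the scale
is exposed so studies needing strictly perturbative couplings can pass
a smaller value.

Retained raster states are separated by a few Monte Carlo sweeps
(default 5) to limit chain autocorrelation — experimental time series
are not MC output, so residual autocorrelation is a modeling artifact
worth suppressing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ising import IsingParameters, MCConfig, metropolis_sample
from .raster import SpikeRaster

__all__ = [
    "GroundTruth",
    "make_paperlike_params",
    "generate_from_ising",
    "generate_independent",
]

DEFAULT_N_UNITS = 60
DEFAULT_N_BINS = 20000


@dataclass
class GroundTruth:
    """A generating model together with the raster sampled from it."""

    params: IsingParameters
    raster: SpikeRaster
    temperature: float
    seed: int


def make_paperlike_params(
    n_units: int = DEFAULT_N_UNITS,
    j_sigma: float | None = None,
    h_location: float = -0.6,
    h_scale: float = 0.6,
    h_skew: float = 0.6,
    seed: int = 0,
) -> IsingParameters:
    """Random parameters shaped like inferred culture models.

    Couplings: ``J_ij ~ Normal(0, j_sigma)``, symmetrized, zero diagonal
    (``j_sigma`` defaults to ``1.2/sqrt(N)``).  Fields: the negative of a
    shifted log-normal, ``h_i = h_location - h_scale * LogNormal(0,
    h_skew)`` — mostly negative and left-skewed, matching sparse firing.
    Deterministic per seed.
    """
    if n_units < 2:
        raise ValueError("need at least 2 units")
    if j_sigma is None:
        j_sigma = 1.2 / np.sqrt(n_units)
    if j_sigma < 0:
        raise ValueError("j_sigma must be >= 0")
    rng = np.random.default_rng(seed)
    raw = rng.normal(0.0, j_sigma, size=(n_units, n_units))
    j = np.triu(raw, k=1)
    j = j + j.T
    h = h_location - h_scale * rng.lognormal(mean=0.0, sigma=h_skew, size=n_units)
    return IsingParameters(fields=h, couplings=j)


def generate_from_ising(
    params: IsingParameters,
    n_bins: int = DEFAULT_N_BINS,
    temperature: float = 1.0,
    config: MCConfig | None = None,
    sample_id: str = "synthetic-ising",
) -> GroundTruth:
    """Sample a raster from a known Ising model (forward model).

    The raster's empirical moments converge to the model's exact
    Boltzmann moments as ``n_bins`` grows.  Reproducible per
    ``config.seed``.
    """
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    config = config or MCConfig(
        equilibration_sweeps=2000,
        sample_sweeps=5 * n_bins,
        thinning=5,
        seed=0,
    )
    if config.n_samples < n_bins:
        raise ValueError(
            f"config yields {config.n_samples} samples < n_bins={n_bins}"
        )
    samples = metropolis_sample(params, temperature, config)[:n_bins]
    raster = SpikeRaster(samples.T, sample_id=sample_id)
    return GroundTruth(
        params=params, raster=raster, temperature=temperature, seed=config.seed
    )


def generate_independent(
    firing_probs: np.ndarray,
    n_bins: int = DEFAULT_N_BINS,
    seed: int = 0,
    sample_id: str = "synthetic-independent",
) -> SpikeRaster:
    """Independent Bernoulli units: s_i(t)=+1 with probability p_i.

    The uncorrelated null: expected means ``2 p_i - 1``, expected
    off-diagonal covariances zero, and a binomial-like simultaneous-spike
    distribution.
    """
    p = np.atleast_1d(np.asarray(firing_probs, dtype=float))
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("firing probabilities must lie strictly in (0, 1)")
    rng = np.random.default_rng(seed)
    spikes = rng.random((p.size, n_bins)) < p[:, None]
    states = np.where(spikes, 1, -1).astype(np.int8)
    return SpikeRaster(states, sample_id=sample_id)
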
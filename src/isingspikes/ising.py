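"""The pairwise Ising energy model and its Boltzmann samplers.

The model assigns each configuration ``{s}`` of ``N`` spins the energy

    H = - sum_i h_i s_i - sum_{i>j} J_ij s_i s_j        (k_B = 1)

and the probability ``P({s}) ~ exp(-H/T)``.  ``h_i`` is the local field
acting on unit ``i`` and ``J_ij`` the symmetric pairwise coupling; each
unordered pair contributes once.  Model moments can be estimated two
ways behind the same :class:`~isingspikes.moments.MomentSet` interface:
single-spin-flip Metropolis Monte Carlo (any ``N``), or exact summation
over all ``2^N`` states (the small-``N`` oracle, with log-sum-exp
stabilization of the Boltzmann weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .moments import MomentSet

__all__ = [
    "IsingParameters",
    "MCConfig",
    "energy",
    "metropolis_sample",
    "mc_moments",
    "exact_moments",
]

_MAX_ENUMERATION_UNITS = 20


@dataclass
class IsingParameters:
    """Local fields ``h_i`` and symmetric couplings ``J_ij`` (zero diagonal).

    ``reference_temperature`` records the operating temperature ``T_o``
    the parameters were inferred at (1 by convention); rescaling ``T``
    rescales ``h`` and ``J`` jointly, so only the ratio matters.
    """

    fields: np.ndarray
    couplings: np.ndarray
    reference_temperature: float = 1.0

    def __post_init__(self):
        h = np.asarray(self.fields, dtype=float)
        j = np.asarray(self.couplings, dtype=float)
        if h.ndim != 1 or h.shape[0] < 2:
            raise ValueError("fields must be a vector of length >= 2")
        if j.shape != (h.shape[0], h.shape[0]):
            raise ValueError("couplings shape does not match fields")
        if not (np.isfinite(h).all() and np.isfinite(j).all()):
            raise ValueError("parameters must be finite")
        if not np.allclose(j, j.T, atol=1e-10):
            raise ValueError("couplings must be symmetric")
        if not np.allclose(np.diag(j), 0.0, atol=1e-12):
            raise ValueError("couplings must have zero diagonal")
        self.fields = h
        self.couplings = (j + j.T) / 2.0
        np.fill_diagonal(self.couplings, 0.0)

    @property
    def n_units(self) -> int:
        return self.fields.shape[0]

    def to_json(self, path) -> None:
        payload = {
            "h": self.fields.tolist(),
            "J": self.couplings.tolist(),
            "T_o": self.reference_temperature,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "IsingParameters":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            fields=np.array(payload["h"], dtype=float),
            couplings=np.array(payload["J"], dtype=float),
            reference_temperature=float(payload.get("T_o", 1.0)),
        )


@dataclass
class MCConfig:
    """Monte Carlo chain settings; all counts are in sweeps (N proposals).

    ``sample_sweeps // thinning`` configurations are retained after
    ``equilibration_sweeps``.  ``seed`` must be set explicitly so every
    chain is reproducible; ``update_order`` picks the proposed site
    uniformly at random or cyclically, and ``rule`` switches between
    Metropolis acceptance and the Glauber heat bath.
    """

    equilibration_sweeps: int = 1000
    sample_sweeps: int = 10000
    thinning: int = 1
    seed: int = 0
    update_order: str = "random"
    rule: str = "metropolis"

    def __post_init__(self):
        if min(self.equilibration_sweeps, self.sample_sweeps, self.thinning) < 1:
            raise ValueError("sweep counts and thinning must be >= 1")
        if self.update_order not in ("random", "sequential"):
            raise ValueError(f"unknown update_order {self.update_order!r}")
        if self.rule not in ("metropolis", "glauber"):
            raise ValueError(f"unknown rule {self.rule!r}")

    @property
    def n_samples(self) -> int:
        return self.sample_sweeps // self.thinning


def energy(state: np.ndarray, params: IsingParameters) -> np.ndarray | float:
    """Energy H of one configuration or a batch (rows = configurations)."""
    s = np.asarray(state, dtype=float)
    single = s.ndim == 1
    s = np.atleast_2d(s)
    if s.shape[1] != params.n_units:
        raise ValueError(
            f"state length {s.shape[1]} does not match N={params.n_units}"
        )
    h_term = s @ params.fields
    j_term = 0.5 * np.einsum("ti,ij,tj->t", s, params.couplings, s)
    out = -(h_term + j_term)
    return float(out[0]) if single else out


def _chain_codes(config: MCConfig) -> tuple[int, int]:
    rule = (
        _kernels.RULE_METROPOLIS
        if config.rule == "metropolis"
        else _kernels.RULE_GLAUBER
    )
    order = (
        _kernels.ORDER_RANDOM
        if config.update_order == "random"
        else _kernels.ORDER_SEQUENTIAL
    )
    return rule, order


def metropolis_sample(
    params: IsingParameters,
    temperature: float,
    config: MCConfig,
    initial_state: np.ndarray | None = None,
) -> np.ndarray:
    """Sample configurations from ``P ~ exp(-H/T)`` by single-flip MCMC.

    Returns an ``(n_samples, N)`` int8 array.  The initial state is
    uniform random +/-1 (from the chain seed) unless a warm start is
    supplied.  Deterministic for a fixed ``config.seed``.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    n = params.n_units
    rng = np.random.default_rng(config.seed)
    if initial_state is None:
        s0 = rng.choice([-1.0, 1.0], size=n)
    else:
        s0 = np.asarray(initial_state, dtype=float).copy()
        if s0.shape != (n,):
            raise ValueError("initial_state length does not match N")
    rule, order = _chain_codes(config)
    # numba's legacy RNG wants a 32-bit seed
    kernel_seed = int(rng.integers(0, 2**31 - 1))
    return _kernels.run_chain(
        params.fields,
        np.ascontiguousarray(params.couplings),
        1.0 / temperature,
        s0,
        config.equilibration_sweeps,
        config.n_samples,
        config.thinning,
        kernel_seed,
        rule,
        order,
    )


def moments_from_samples(
    samples: np.ndarray,
    include_triplets: bool = False,
    n_blocks: int = 20,
    source: str = "model",
) -> MomentSet:
    """Moment estimates (with blocking standard errors) from sampled states.

    Standard errors come from ``n_blocks`` contiguous blocks of the
    chain, which absorbs residual autocorrelation that a naive
    ``std/sqrt(n)`` would miss.
    """
    x = samples.astype(np.float64)
    n_samples, n = x.shape
    m = x.mean(axis=0)
    c = x.T @ x / n_samples - np.outer(m, m)
    c = (c + c.T) / 2.0
    trip = None
    if include_triplets:
        xc = np.ascontiguousarray(x - m)
        trip = _kernels.centered_triplet_means(xc)

    mean_se = cov_se = trip_se = None
    n_blocks = min(n_blocks, n_samples)
    if n_blocks >= 2:
        blocks = np.array_split(np.arange(n_samples), n_blocks)
        bm = np.empty((n_blocks, n))
        bc = np.empty((n_blocks, n, n))
        bt = (
            np.empty((n_blocks, n * (n - 1) * (n - 2) // 6))
            if include_triplets
            else None
        )
        for b, idx in enumerate(blocks):
            xb = x[idx]
            mb = xb.mean(axis=0)
            bm[b] = mb
            bc[b] = xb.T @ xb / idx.size - np.outer(mb, mb)
            if include_triplets:
                bt[b] = _kernels.centered_triplet_means(
                    np.ascontiguousarray(xb - mb)
                )
        mean_se = bm.std(axis=0, ddof=1) / np.sqrt(n_blocks)
        cov_se = bc.std(axis=0, ddof=1) / np.sqrt(n_blocks)
        if include_triplets:
            trip_se = bt.std(axis=0, ddof=1) / np.sqrt(n_blocks)
    return MomentSet(
        means=m,
        covariances=c,
        triplets=trip,
        source=source,
        n_samples=n_samples,
        mean_se=mean_se,
        cov_se=cov_se,
        triplet_se=trip_se,
    )


def mc_moments(
    params: IsingParameters,
    temperature: float,
    config: MCConfig,
    include_triplets: bool = False,
    initial_state: np.ndarray | None = None,
    n_blocks: int = 20,
) -> MomentSet:
    """Monte Carlo estimates of model means, covariances and triplets."""
    samples = metropolis_sample(params, temperature, config, initial_state)
    return moments_from_samples(samples, include_triplets, n_blocks)


def enumerate_states(n_units: int) -> np.ndarray:
    """All 2^N spin configurations as a (2^N, N) float matrix of +/-1."""
    codes = np.arange(2**n_units, dtype=np.int64)
    bits = (codes[:, None] >> np.arange(n_units)) & 1
    return (2.0 * bits - 1.0).astype(np.float64)


def boltzmann_weights(
    params: IsingParameters, temperature: float, states: np.ndarray
) -> np.ndarray:
    """Normalized Boltzmann probabilities over the supplied states."""
    log_w = -energy(states, params) / temperature
    log_w -= log_w.max()  # log-sum-exp stabilization
    w = np.exp(log_w)
    return w / w.sum()


def exact_moments(
    params: IsingParameters,
    temperature: float,
    include_triplets: bool = False,
) -> MomentSet:
    """Exact model moments by summation over all 2^N states (N <= 20)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    n = params.n_units
    if n > _MAX_ENUMERATION_UNITS:
        raise ValueError(
            f"exact enumeration limited to N <= {_MAX_ENUMERATION_UNITS} "
            f"(2^{n} states requested); use mc_moments for larger systems"
        )
    states = enumerate_states(n)
    w = boltzmann_weights(params, temperature, states)
    m = w @ states
    second = states.T @ (states * w[:, None])
    c = second - np.outer(m, m)
    c = (c + c.T) / 2.0
    trip = None
    if include_triplets:
        # sum_t w_t x_i x_j x_k == mean over rows of (w^{1/3} x) products
        xc = (states - m) * np.cbrt(w)[:, None]
        trip = _kernels.centered_triplet_means(np.ascontiguousarray(xc)) * states.shape[0]
    return MomentSet(
        means=m,
        covariances=c,
        triplets=trip,
        source="model",
        n_samples=states.shape[0],
    )
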
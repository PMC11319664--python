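"""Numba kernels: single-spin-flip Monte Carlo chains and triplet moments.

The chain kernel evaluates every proposal's energy change directly from
the current configuration through the local field
``f_i = h_i + sum_j J_ij s_j`` (an O(N) dot product), so no incremental
energy bookkeeping exists that could drift.  Randomness comes from
numba's own ``np.random`` state, seeded once per call — a fixed seed
reproduces the chain bit-for-bit.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# update rules / orders encoded as ints for the jitted kernel
RULE_METROPOLIS = 0
RULE_GLAUBER = 1
ORDER_RANDOM = 0
ORDER_SEQUENTIAL = 1


@njit(cache=True)
def _sweep(s, h, J, beta, n_units, rule, order):
    """One sweep = n_units proposed single-spin flips, in place."""
    for k in range(n_units):
        if order == ORDER_RANDOM:
            i = np.random.randint(n_units)
        else:
            i = k
        f = h[i]
        for j in range(n_units):
            f += J[i, j] * s[j]
        d_e = 2.0 * s[i] * f
        if rule == RULE_METROPOLIS:
            accept = d_e <= 0.0 or np.random.random() < np.exp(-beta * d_e)
        else:  # Glauber heat bath
            accept = np.random.random() < 1.0 / (1.0 + np.exp(beta * d_e))
        if accept:
            s[i] = -s[i]


@njit(cache=True)
def run_chain(h, J, beta, state0, n_eq_sweeps, n_keep, thin_sweeps, seed, rule, order):
    """Run a chain and return ``n_keep`` retained configurations.

    ``state0`` (float64, +/-1) is the initial configuration and is not
    modified; ``thin_sweeps`` full sweeps separate retained samples after
    ``n_eq_sweeps`` of equilibration.
    """
    np.random.seed(seed)
    n_units = h.shape[0]
    s = state0.copy()
    for _ in range(n_eq_sweeps):
        _sweep(s, h, J, beta, n_units, rule, order)
    out = np.empty((n_keep, n_units), dtype=np.int8)
    for t in range(n_keep):
        for _ in range(thin_sweeps):
            _sweep(s, h, J, beta, n_units, rule, order)
        for i in range(n_units):
            out[t, i] = np.int8(s[i])
    return out


@njit(cache=True)
def centered_triplet_means(xc):
    """Mean over rows of x_i*x_j*x_k for all i<j<k of a centered matrix.

    ``xc`` has shape (n_samples, n_units); returns the C(n_units, 3)
    connected third central moments in lexicographic (i<j<k) order.
    """
    n_samples, n_units = xc.shape
    n_triples = n_units * (n_units - 1) * (n_units - 2) // 6
    out = np.zeros(n_triples, dtype=np.float64)
    for t in range(n_samples):
        idx = 0
        for i in range(n_units):
            xi = xc[t, i]
            for j in range(i + 1, n_units):
                xij = xi * xc[t, j]
                for k in range(j + 1, n_units):
                    out[idx] += xij * xc[t, k]
                    idx += 1
    return out / n_samples
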
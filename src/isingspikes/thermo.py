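"""Thermodynamic characterization of a learned Ising model.

For a configuration ``{s}`` the per-spin magnetization is
``M = (1/N) sum_i s_i`` and the per-spin energy ``E = H/N`` with the
Hamiltonian ``H = -sum_i h_i s_i - sum_{i>j} J_ij s_i s_j``.  (Only the
variance of E enters the observables below, so the overall sign
convention is immaterial; we report the Hamiltonian per spin.)  From the
fluctuation-dissipation relations,

    C(T)   = (1/T^2) ( <E^2> - <E>^2 )          specific heat
    chi(T) = (1/T)   ( <M^2> - <M>^2 )          susceptibility

both in the per-spin convention exactly as written (no extra factor of
N; ``extensive=True`` multiplies by N for comparison with textbook
conventions).  The temperatures at which C or chi peak locate the
model's crossover temperature ``T_c*``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .ising import (
    IsingParameters,
    MCConfig,
    boltzmann_weights,
    energy,
    enumerate_states,
    metropolis_sample,
)

__all__ = [
    "ThermoPoint",
    "ThermoCurve",
    "PeakResult",
    "HysteresisReport",
    "thermo_observables",
    "exact_thermo_observables",
    "temperature_sweep",
    "find_peak",
    "hysteresis_check",
]


@dataclass
class ThermoPoint:
    """Observables at a single temperature, with replicate standard errors."""

    temperature: float
    magnetization: float
    energy: float
    specific_heat: float
    susceptibility: float
    magnetization_se: float
    energy_se: float
    specific_heat_se: float
    susceptibility_se: float


@dataclass
class ThermoCurve:
    """Observables on a temperature grid.

    ``sweep_direction`` records how chains were initialized: fresh random
    states per temperature ("independent") or warm-started from the
    neighboring grid point ("ascending"/"descending").
    """

    temperatures: np.ndarray
    magnetization: np.ndarray
    energy: np.ndarray
    specific_heat: np.ndarray
    susceptibility: np.ndarray
    magnetization_se: np.ndarray
    energy_se: np.ndarray
    specific_heat_se: np.ndarray
    susceptibility_se: np.ndarray
    sweep_direction: str = "independent"

    def __post_init__(self):
        t = np.asarray(self.temperatures, dtype=float)
        if t.ndim != 1 or t.size < 1 or np.any(np.diff(t) <= 0):
            raise ValueError("temperature grid must be strictly increasing")

    def column(self, observable: str) -> np.ndarray:
        return getattr(self, observable)


@dataclass
class PeakResult:
    """Location and height of an observable's maximum over temperature."""

    t_peak: float
    height: float
    grid_t_peak: float
    grid_height: float
    on_boundary: bool


@dataclass
class HysteresisReport:
    """Initial-condition dependence of M(T) across sweep protocols."""

    temperatures: np.ndarray
    magnetization_ascending: np.ndarray
    magnetization_descending: np.ndarray
    magnetization_independent: np.ndarray
    combined_se: np.ndarray
    max_discrepancy: float
    max_discrepancy_in_se: float
    hysteresis_detected: bool


def _per_spin_observables(samples: np.ndarray, params: IsingParameters):
    s = samples.astype(float)
    m = s.mean(axis=1)  # per-spin magnetization per configuration
    e = energy(s, params) / params.n_units
    return m, e


def _point_from_runs(
    t: float,
    m_runs: list[np.ndarray],
    e_runs: list[np.ndarray],
    n_units: int,
    extensive: bool,
    abs_magnetization: bool = False,
) -> ThermoPoint:
    reps = len(m_runs)
    chi_scale = n_units if extensive else 1.0
    if abs_magnetization:
        m_runs = [np.abs(m) for m in m_runs]
    vals = np.array(
        [
            [
                m.mean(),
                e.mean(),
                e.var() / t**2,
                chi_scale * m.var() / t,
            ]
            for m, e in zip(m_runs, e_runs)
        ]
    )
    mean = vals.mean(axis=0)
    se = (
        vals.std(axis=0, ddof=1) / np.sqrt(reps)
        if reps > 1
        else np.full(4, np.nan)
    )
    return ThermoPoint(
        temperature=t,
        magnetization=float(mean[0]),
        energy=float(mean[1]),
        specific_heat=float(mean[2]),
        susceptibility=float(mean[3]),
        magnetization_se=float(se[0]),
        energy_se=float(se[1]),
        specific_heat_se=float(se[2]),
        susceptibility_se=float(se[3]),
    )


def thermo_observables(
    params: IsingParameters,
    temperature: float,
    config: MCConfig,
    n_replicates: int = 8,
    extensive: bool = False,
    initial_state: np.ndarray | None = None,
    abs_magnetization: bool = False,
) -> ThermoPoint:
    """Monte Carlo estimate of (<M>, <E>, C, chi) at one temperature.

    Standard errors come from ``n_replicates`` independent chains
    (seeds derived from ``config.seed``), which also absorbs
    autocorrelation within a chain.

    ``abs_magnetization=True`` replaces M by |M| in the magnetization
    and susceptibility — the standard finite-size treatment of
    zero-field models, whose ordered phase is two-fold degenerate: the
    plain variance of M is then dominated by inter-well flips and grows
    monotonically as T decreases, masking the transition peak.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be > 0, got {temperature}")
    m_runs, e_runs = [], []
    for r in range(n_replicates):
        cfg = MCConfig(
            equilibration_sweeps=config.equilibration_sweeps,
            sample_sweeps=config.sample_sweeps,
            thinning=config.thinning,
            seed=int((config.seed + 104729 * (r + 1)) % 2**31),
            update_order=config.update_order,
            rule=config.rule,
        )
        samples = metropolis_sample(params, temperature, cfg, initial_state)
        m, e = _per_spin_observables(samples, params)
        m_runs.append(m)
        e_runs.append(e)
    return _point_from_runs(
        temperature, m_runs, e_runs, params.n_units, extensive, abs_magnetization
    )


def exact_thermo_observables(
    params: IsingParameters,
    temperature: float,
    extensive: bool = False,
    abs_magnetization: bool = False,
) -> ThermoPoint:
    """Enumeration oracle for (<M>, <E>, C, chi) at small N."""
    states = enumerate_states(params.n_units)
    w = boltzmann_weights(params, temperature, states)
    m = states.mean(axis=1)
    if abs_magnetization:
        m = np.abs(m)
    e = energy(states, params) / params.n_units
    mm, ee = w @ m, w @ e
    var_m = w @ (m - mm) ** 2
    var_e = w @ (e - ee) ** 2
    chi_scale = params.n_units if extensive else 1.0
    return ThermoPoint(
        temperature=temperature,
        magnetization=float(mm),
        energy=float(ee),
        specific_heat=float(var_e / temperature**2),
        susceptibility=float(chi_scale * var_m / temperature),
        magnetization_se=0.0,
        energy_se=0.0,
        specific_heat_se=0.0,
        susceptibility_se=0.0,
    )


def default_temperature_grid(
    t_min: float = 0.5, t_max: float = 2.0, step: float = 0.02
) -> np.ndarray:
    return np.round(np.arange(t_min, t_max + step / 2, step), 10)


def temperature_sweep(
    params: IsingParameters,
    t_grid: np.ndarray,
    config: MCConfig,
    mode: str = "independent",
    n_replicates: int = 8,
    extensive: bool = False,
    abs_magnetization: bool = False,
) -> ThermoCurve:
    """Observables across a temperature grid.

    ``independent`` starts a fresh random chain at every temperature;
    ``ascending``/``descending`` traverse the grid warm-starting each
    replicate's chain from its final configuration at the previous
    temperature (the protocol hysteresis checks compare).
    ``abs_magnetization`` as in :func:`thermo_observables` (use for
    zero-field models).
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if np.any(np.diff(t_grid) <= 0):
        raise ValueError("temperature grid must be strictly increasing")
    if mode not in ("independent", "ascending", "descending"):
        raise ValueError(f"unknown sweep mode {mode!r}")
    if np.any(t_grid <= 0):
        raise ValueError("temperatures must be > 0")

    order = np.arange(t_grid.size)
    if mode == "descending":
        order = order[::-1]

    n = params.n_units
    warm: list[np.ndarray | None] = [None] * n_replicates
    points: dict[int, ThermoPoint] = {}
    for gi in order:
        t = float(t_grid[gi])
        m_runs, e_runs = [], []
        for r in range(n_replicates):
            cfg = MCConfig(
                equilibration_sweeps=config.equilibration_sweeps,
                sample_sweeps=config.sample_sweeps,
                thinning=config.thinning,
                seed=int((config.seed + 104729 * (r + 1) + 15485863 * gi) % 2**31),
                update_order=config.update_order,
                rule=config.rule,
            )
            init = warm[r] if mode != "independent" else None
            samples = metropolis_sample(params, t, cfg, init)
            if mode != "independent":
                warm[r] = samples[-1].astype(float)
            m, e = _per_spin_observables(samples, params)
            m_runs.append(m)
            e_runs.append(e)
        points[gi] = _point_from_runs(
            t, m_runs, e_runs, n, extensive, abs_magnetization
        )

    def col(attr):
        return np.array([getattr(points[i], attr) for i in range(t_grid.size)])

    return ThermoCurve(
        temperatures=t_grid,
        magnetization=col("magnetization"),
        energy=col("energy"),
        specific_heat=col("specific_heat"),
        susceptibility=col("susceptibility"),
        magnetization_se=col("magnetization_se"),
        energy_se=col("energy_se"),
        specific_heat_se=col("specific_heat_se"),
        susceptibility_se=col("susceptibility_se"),
        sweep_direction=mode,
    )


def find_peak(curve: ThermoCurve, observable: str = "specific_heat") -> PeakResult:
    """Locate T_c*: grid argmax refined by a local quadratic fit.

    The refinement fits a parabola through the three points around the
    grid maximum (exact for parabolic peaks).  A maximum on the grid
    boundary is returned as-is with a warning, since the peak is not
    bracketed.
    """
    t = curve.temperatures
    if t.size < 5:
        raise ValueError("peak finding needs at least 5 grid points")
    y = curve.column(observable)
    i = int(np.argmax(y))
    grid_t, grid_h = float(t[i]), float(y[i])
    if i == 0 or i == t.size - 1:
        warnings.warn(
            f"{observable} maximum lies on the grid boundary (T={grid_t}); "
            "peak not bracketed",
            stacklevel=2,
        )
        return PeakResult(grid_t, grid_h, grid_t, grid_h, on_boundary=True)
    coeffs = np.polyfit(t[i - 1 : i + 2], y[i - 1 : i + 2], 2)
    if coeffs[0] >= 0:  # degenerate (flat/colinear) neighborhood
        return PeakResult(grid_t, grid_h, grid_t, grid_h, on_boundary=False)
    t_peak = float(-coeffs[1] / (2 * coeffs[0]))
    height = float(np.polyval(coeffs, t_peak))
    return PeakResult(t_peak, height, grid_t, grid_h, on_boundary=False)


def hysteresis_check(
    params: IsingParameters,
    t_grid: np.ndarray,
    config: MCConfig,
    n_replicates: int = 6,
    extensive: bool = False,
) -> HysteresisReport:
    """Compare M(T) between ascending, descending and independent sweeps.

    Reports the largest pairwise discrepancy in units of the combined
    standard error; a maximum above 3 combined SE at any temperature is
    flagged as hysteresis (initial-condition dependence), the signature
    of a first-order transition.
    """
    curves = {
        mode: temperature_sweep(
            params, t_grid, config, mode, n_replicates, extensive
        )
        for mode in ("ascending", "descending", "independent")
    }
    m_a = curves["ascending"].magnetization
    m_d = curves["descending"].magnetization
    m_i = curves["independent"].magnetization
    se = np.sqrt(
        curves["ascending"].magnetization_se ** 2
        + curves["descending"].magnetization_se ** 2
    )
    disc = np.max(
        np.vstack([np.abs(m_a - m_d), np.abs(m_a - m_i), np.abs(m_d - m_i)]),
        axis=0,
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        in_se = disc / np.where(se > 0, se, np.nan)
    max_in_se = float(np.nanmax(in_se))
    return HysteresisReport(
        temperatures=np.asarray(t_grid, dtype=float),
        magnetization_ascending=m_a,
        magnetization_descending=m_d,
        magnetization_independent=m_i,
        combined_se=se,
        max_discrepancy=float(disc.max()),
        max_discrepancy_in_se=max_in_se,
        hysteresis_detected=bool(max_in_se > 3.0),
    )
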
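"""Binarized spike rasters: container, text I/O, and time-shuffling.

A raster is an ``N x M`` matrix of spin-coded spike states: rows are
electrodes (or units), columns are time bins, entries are +1 (spike) or
-1 (silence).  Files use whitespace- or comma-delimited text with values
in {-1, +1} or {0, 1}; lines starting with ``#`` are comments.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SpikeRaster",
    "RasterFormatError",
    "load_raster",
    "save_raster",
    "shuffle_raster",
]


class RasterFormatError(ValueError):
    """Raised when a raster file or array violates the +/-1 contract."""


@dataclass
class SpikeRaster:
    """An ``N x M`` matrix of spin states ``s_i(t) in {-1, +1}``.

    Parameters
    ----------
    states
        Integer matrix, rows = units, columns = time bins.
    sample_id
        Free-form label carried through the analysis.
    bin_width
        Optional bin duration in seconds (metadata only).
    """

    states: np.ndarray
    sample_id: str = ""
    bin_width: float | None = None

    def __post_init__(self):
        states = np.asarray(self.states)
        if states.ndim != 2:
            raise RasterFormatError(f"raster must be 2-D, got shape {states.shape}")
        bad = ~np.isin(states, (-1, 1))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise RasterFormatError(
                f"non-spin entry {states[r, c]!r} at row {r}, column {c}; "
                "states must be -1 or +1"
            )
        n, m = states.shape
        if n < 2:
            raise RasterFormatError(f"need at least 2 units, got N={n}")
        if m < 1:
            raise RasterFormatError("need at least 1 time bin")
        object.__setattr__(self, "states", states.astype(np.int8))

    @property
    def n_units(self) -> int:
        return self.states.shape[0]

    @property
    def n_bins(self) -> int:
        return self.states.shape[1]


def _coerce_binary(values: np.ndarray, encoding: str) -> np.ndarray:
    """Map a raw numeric matrix onto {-1,+1} according to ``encoding``."""
    vals = np.asarray(values)
    if not np.isfinite(vals).all():
        raise RasterFormatError("raster contains non-finite entries")
    rounded = np.rint(vals)
    if not np.allclose(vals, rounded):
        bad = np.argwhere(vals != rounded)[0]
        raise RasterFormatError(
            f"non-integer entry {vals[tuple(bad)]} at row {bad[0]}, column {bad[1]}"
        )
    vals = rounded.astype(np.int64)
    uniq = set(np.unique(vals).tolist())

    if encoding == "auto":
        # all-ones input is ambiguous; treat as +1 spins
        encoding = "zero_one" if uniq <= {0, 1} and 0 in uniq else "plus_minus_one"

    if encoding == "zero_one":
        allowed = {0, 1}
    elif encoding == "plus_minus_one":
        allowed = {-1, 1}
    else:
        raise ValueError(f"unknown encoding {encoding!r}")

    if not uniq <= allowed:
        offending = sorted(uniq - allowed)[0]
        r, c = np.argwhere(vals == offending)[0]
        raise RasterFormatError(
            f"entry {offending} at row {r}, column {c} not in {sorted(allowed)} "
            f"for encoding {encoding!r}"
        )
    if encoding == "zero_one":
        vals = 2 * vals - 1
    return vals.astype(np.int8)


def load_raster(
    path,
    encoding: str = "auto",
    sample_id: str | None = None,
    bin_width: float | None = None,
) -> SpikeRaster:
    """Read a delimited-text raster (rows = units, columns = bins).

    ``encoding`` is ``"plus_minus_one"``, ``"zero_one"`` or ``"auto"``
    (detect: a matrix whose entries are all 0/1 with at least one 0 is
    taken as 0/1 and mapped 0 -> -1, 1 -> +1).
    """
    with open(path) as fh:
        text = fh.read()
    # accept comma- or whitespace-delimited uniformly
    cleaned = text.replace(",", " ")
    try:
        values = np.loadtxt(io.StringIO(cleaned), comments="#", ndmin=2)
    except ValueError as exc:
        raise RasterFormatError(f"could not parse {path}: {exc}") from exc
    states = _coerce_binary(values, encoding)
    return SpikeRaster(
        states,
        sample_id=sample_id if sample_id is not None else str(path),
        bin_width=bin_width,
    )


def save_raster(raster: SpikeRaster, path, encoding: str = "plus_minus_one") -> None:
    """Write a raster as whitespace-delimited integers."""
    states = raster.states
    if encoding == "zero_one":
        states = (states + 1) // 2
    elif encoding != "plus_minus_one":
        raise ValueError(f"unknown encoding {encoding!r}")
    header = f"raster sample_id={raster.sample_id} N={raster.n_units} M={raster.n_bins}"
    np.savetxt(path, states, fmt="%d", header=header)


def shuffle_raster(raster: SpikeRaster, seed: int) -> SpikeRaster:
    """Independently permute each unit's time series.

    Destroys all cross-unit (and temporal) correlation structure while
    preserving every unit's spike count, hence its mean activity, exactly.
    Deterministic for a fixed ``seed``.
    """
    rng = np.random.default_rng(seed)
    shuffled = np.empty_like(raster.states)
    for i in range(raster.n_units):
        shuffled[i] = rng.permutation(raster.states[i])
    return SpikeRaster(
        shuffled,
        sample_id=f"{raster.sample_id}/shuffled",
        bin_width=raster.bin_width,
    )
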
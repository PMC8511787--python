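"""Scalar time-series container, file I/O, resampling and derivatives.

The modelling pipeline assumes a single uniformly sampled scalar signal
``x(t)`` with a known sampling period ``dt``.  Timestamps are never trusted
from files: the user states ``dt`` explicitly, and missing values are an
error rather than something to impute, because the delay-embedding step
requires complete uniform sampling.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

__all__ = [
    "TimeSeries",
    "load_series",
    "write_series",
    "resample_spline",
    "fd_derivatives",
]


@dataclass(frozen=True)
class TimeSeries:
    """A uniformly sampled scalar signal.

    Parameters
    ----------
    values : ndarray
        The samples ``x(t0 + k*dt)``, in signal units.
    dt : float
        Sampling period, ``> 0``.
    t0 : float
        Time of the first sample.
    """

    values: np.ndarray
    dt: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1:
            raise ValueError("values must be one-dimensional")
        if v.size < 2:
            raise ValueError("a time series needs at least 2 samples")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        """The uniform sample grid ``t0 + k*dt``."""
        return self.t0 + self.dt * np.arange(self.values.size)

    @property
    def t_end(self) -> float:
        return self.t0 + self.dt * (self.values.size - 1)


def _delimiter_for(path: str) -> str:
    return "\t" if os.path.splitext(path)[1].lower() in {".tsv", ".tab"} else ","


def load_series(path: str, column: str | int, dt: float, t0: float = 0.0) -> TimeSeries:
    """Read one numeric column of a CSV/TSV file as a :class:`TimeSeries`.

    ``column`` selects by header name (str) or 0-based position (int).  The
    delimiter is chosen from the file extension (``.tsv``/``.tab`` means
    tab, anything else comma).  Any missing or non-numeric cell in the
    selected column is an error; sampling metadata (``dt``, ``t0``) is
    supplied by the caller, never inferred from a timestamp column.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    sep = _delimiter_for(path)
    header = 0 if isinstance(column, str) else None
    df = pd.read_csv(path, sep=sep, header=header, skip_blank_lines=False,
                     float_precision="round_trip")
    if isinstance(column, str):
        if column not in df.columns:
            raise KeyError(f"column {column!r} not found; have {list(df.columns)}")
        raw = df[column]
    else:
        if not (0 <= column < df.shape[1]):
            raise IndexError(f"column index {column} out of range for {df.shape[1]} columns")
        raw = df.iloc[:, column]
        # a header row of a headerless read would surface as a non-numeric
        # first entry; retry with header if every later row parses
        if raw.size and isinstance(raw.iloc[0], str):
            try:
                float(raw.iloc[0])
            except ValueError:
                df = pd.read_csv(path, sep=sep, header=0, skip_blank_lines=False,
                                 float_precision="round_trip")
                raw = df.iloc[:, column]
    vals = pd.to_numeric(raw, errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise ValueError(f"missing value at row {int(bad[0])}")
    if vals.size < 2:
        raise ValueError("file holds fewer than 2 rows")
    return TimeSeries(vals, dt=dt, t0=t0)


def write_series(ts: TimeSeries, path: str) -> None:
    """Write ``t,x`` at full double precision (delimiter from extension).

    Values are written in shortest-roundtrip decimal form, so a load/write
    cycle preserves finite doubles bit for bit.
    """
    sep = _delimiter_for(path)
    df = pd.DataFrame({"t": ts.times, "x": ts.values})
    df.to_csv(path, sep=sep, index=False)


def resample_spline(ts: TimeSeries, new_dt: float) -> TimeSeries:
    """Resample through a not-a-knot cubic spline on a new uniform grid.

    The new grid starts at ``ts.t0`` and never exceeds the original final
    time, so no extrapolation occurs.  Not-a-knot end conditions reproduce
    cubic polynomials exactly and pass through every original sample.
    """
    if not (new_dt > 0):
        raise ValueError("new_dt must be > 0")
    if len(ts) < 4:
        raise ValueError("cubic resampling needs at least 4 samples")
    n_new = int(np.floor((ts.t_end - ts.t0) / new_dt + 1e-9)) + 1
    if n_new < 2:
        raise ValueError("new grid would contain fewer than 2 points")
    spline = CubicSpline(ts.times, ts.values, bc_type="not-a-knot")
    grid = ts.t0 + new_dt * np.arange(n_new)
    return TimeSeries(spline(grid), dt=new_dt, t0=ts.t0)


def fd_derivatives(v: np.ndarray, dt: float, max_order: int) -> list[np.ndarray]:
    """Finite-difference derivatives of orders ``1..max_order``.

    Each order applies a second-order central stencil in the interior and a
    one-sided second-order stencil at the two boundary points; order ``k``
    is obtained by applying the first-derivative operator ``k`` times.  All
    returned vectors have the same length as ``v`` and approximate the
    ``k``-th time derivative (the ``dt**k`` scaling is already applied).
    """
    v = np.asarray(v, dtype=float)
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if v.ndim != 1 or v.size <= 2 * max_order:
        raise ValueError(
            f"vector of length {v.size} too short for derivative order {max_order}"
        )
    out: list[np.ndarray] = []
    d = v
    for _ in range(max_order):
        d = np.gradient(d, dt, edge_order=2)
        out.append(d)
    return out
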
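"""Hankel (time-delay) matrices: construction, centring, splitting, checks.

A scalar series ``x_0..x_{q-1}`` is stacked into the m-row Hankel matrix
``H[i, j] = x[i + j]`` whose columns are short delay windows.  Centring
subtracts the middle delay row ``h0`` so that the singular vectors of the
transpose align with trajectory *derivative* directions (the moving
Frenet-Serret frame) instead of the trajectory itself.  The sampling
adequacy check asks whether the delay window ``m*dt`` is short relative to
ratios of successive derivative norms of ``h0`` — the regime in which the
fitted linear model is expected to come out antisymmetric tridiagonal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .signals import TimeSeries, fd_derivatives

__all__ = [
    "DelayEmbedding",
    "HankelPair",
    "SamplingReport",
    "build_hankel",
    "centre",
    "split_pair",
    "check_sampling",
]


@dataclass(frozen=True)
class DelayEmbedding:
    """An m x n Hankel matrix, optionally centred on its middle row."""

    H: np.ndarray
    dt: float
    centred: bool = False
    h0: np.ndarray | None = None

    @property
    def m(self) -> int:
        return self.H.shape[0]

    @property
    def n(self) -> int:
        return self.H.shape[1]

    @property
    def centre_index(self) -> int:
        """0-based index of the middle delay row (odd m only)."""
        if self.m % 2 == 0:
            raise ValueError("centre row undefined for even m")
        return (self.m - 1) // 2


@dataclass(frozen=True)
class HankelPair:
    """Column-shifted slices H1 = H[:, :-1], H2 = H[:, 1:] of one parent."""

    H1: np.ndarray
    H2: np.ndarray
    dt: float
    centred: bool


@dataclass(frozen=True)
class SamplingReport:
    """Outcome of the delay-window adequacy check.

    ``window`` is ``m*dt``; ``ratios[k]`` is ``(k+2)*||h0^(k+1)|| / ||h0^(k+2)||``
    (so the first entry is ``2||h0'||/||h0''||``).  The check passes when the
    window is below ``margin`` times the first ratio.
    """

    window: float
    ratios: np.ndarray
    margin: float
    passed: bool
    warning: str | None = None


def build_hankel(ts: TimeSeries, m: int) -> DelayEmbedding:
    """Stack ``m`` time-shifted copies of the series into a Hankel matrix.

    ``H[i, j] = x[i + j]`` with shape ``m x (q - m + 1)``.
    """
    q = len(ts)
    if not (2 <= m <= q - 1):
        raise ValueError(f"delay count m={m} must satisfy 2 <= m <= q-1={q - 1}")
    n = q - m + 1
    # stride trick view, copied so the embedding owns its memory
    H = np.lib.stride_tricks.sliding_window_view(ts.values, n)[:m].copy()
    return DelayEmbedding(H=H, dt=ts.dt, centred=False)


def centre(emb: DelayEmbedding) -> DelayEmbedding:
    """Subtract the middle delay row ``h0`` from every row.

    Requires an odd number of rows so the middle row is unique.  The row is
    retained as ``h0`` for curvature scaling and signal reconstruction.
    """
    if emb.centred:
        raise ValueError("embedding is already centred")
    if emb.m % 2 == 0:
        raise ValueError("centre row undefined for even m; use an odd delay count")
    c = (emb.m - 1) // 2
    h0 = emb.H[c].copy()
    return DelayEmbedding(H=emb.H - h0[None, :], dt=emb.dt, centred=True, h0=h0)


def split_pair(emb: DelayEmbedding) -> HankelPair:
    """Split into the column-shifted pair (columns ``0..n-2`` and ``1..n-1``)."""
    if emb.n < 2:
        raise ValueError("need at least 2 columns to split")
    return HankelPair(
        H1=emb.H[:, :-1], H2=emb.H[:, 1:], dt=emb.dt, centred=emb.centred
    )


def check_sampling(
    emb: DelayEmbedding, orders: int = 2, margin: float = 0.1
) -> SamplingReport:
    """Check that the delay window is short enough for frame extraction.

    The Taylor expansion of the delay trajectory about its centre requires
    ``m*dt`` to be well below ``2||h0'||/||h0''||`` (and the further, larger,
    ratios ``(k+1)||h0^(k)||/||h0^(k+1)||``, which in practice need not be
    checked).  "Well below" is operationalised as ``window < margin * ratio``
    with ``margin=0.1`` by default.
    """
    if not emb.centred or emb.h0 is None:
        raise ValueError("sampling check needs a centred embedding (h0 required)")
    if orders < 1:
        raise ValueError("orders must be >= 1")
    derivs = fd_derivatives(emb.h0, emb.dt, orders + 1)
    norms = [float(np.linalg.norm(d)) for d in derivs]
    ratios = np.empty(orders)
    warning = None
    for k in range(orders):
        num, den = norms[k], norms[k + 1]
        if den == 0.0:
            ratios[k] = np.inf
            warning = f"derivative of order {k + 2} vanishes; ratio reported as inf"
        else:
            ratios[k] = (k + 2) * num / den
    window = emb.m * emb.dt
    passed = bool(window < margin * ratios[0])
    return SamplingReport(
        window=window, ratios=ratios, margin=margin, passed=passed, warning=warning
    )
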
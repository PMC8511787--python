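"""Frenet-Serret frames, Gram-determinant curvatures and structure metrics.

A smooth trajectory ``gamma(t)`` with linearly independent derivatives
carries a moving orthonormal frame (Gram-Schmidt on the successive
derivatives).  The frame evolves as ``dQ/dt = ||gamma'|| K Q`` where ``K``
is antisymmetric tridiagonal with the intrinsic curvatures ``kappa_i`` on
its off-diagonals.  For delay-coordinate models the same matrix appears as
``K = A / ||h0'||``, so curvatures can be read off a fitted HAVOK/sHAVOK
model and cross-checked against the exact Gram-determinant formula

    kappa_i = D_{i+1} D_{i-1} / (D_i^2 ||gamma'||),    D_0 = 1,

with ``D_i`` the square root of the Gram determinant of the first i
derivative vectors.  The structure metrics quantify how antisymmetric and
how tridiagonal a fitted dynamics matrix actually is.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .embedding import DelayEmbedding
from .havok import HavokModel
from .signals import fd_derivatives

__all__ = [
    "FrenetFrame",
    "CurvatureEstimate",
    "StructureReport",
    "frenet_frame",
    "gram_curvatures",
    "curvature_from_model",
    "curvature_matrix",
    "structure_report",
]

_DEP_TOL = 1e-10


@dataclass(frozen=True)
class FrenetFrame:
    """Rows of E are the orthonormal frame vectors e_1..e_r."""

    E: np.ndarray


@dataclass(frozen=True)
class CurvatureEstimate:
    """Curvatures, trajectory speed and the curvature matrix K.

    ``kappas`` are the non-negative curvatures ``kappa_1..kappa_{r-1}``
    (units 1/length in trajectory space); ``speed`` is ``||gamma'||``;
    ``K`` is the r x r curvature matrix — the exact antisymmetric
    tridiagonal template when built from curvatures alone, or ``A/speed``
    when extracted from a fitted model (then only approximately so).
    """

    kappas: np.ndarray
    speed: float
    K: np.ndarray


@dataclass(frozen=True)
class StructureReport:
    """How far a dynamics matrix is from antisymmetric tridiagonal form.

    ``antisym_index = ||A + A^T||_F / (2 ||A||_F)`` and ``tridiag_index``
    is the fraction of squared Frobenius mass outside the tridiagonal
    band; both lie in [0, 1] and vanish exactly for an antisymmetric
    tridiagonal matrix.  ``max_real`` is the largest eigenvalue real part.
    """

    antisym_index: float
    tridiag_index: float
    max_real: float


def frenet_frame(derivs: list[np.ndarray]) -> FrenetFrame:
    """Orthonormal frame from successive derivatives via modified Gram-Schmidt.

    ``derivs[0]`` is the first derivative; ``e_1`` is its unit vector.  A
    derivative whose residual after projection is below ``1e-10`` of its
    norm is declared linearly dependent and rejected.
    """
    if len(derivs) < 1:
        raise ValueError("need at least one derivative vector")
    vs = [np.asarray(v, dtype=float) for v in derivs]
    n = vs[0].size
    if any(v.shape != (n,) for v in vs):
        raise ValueError("derivative vectors must share one length")
    E = np.empty((len(vs), n))
    for i, v in enumerate(vs):
        w = v.copy()
        for j in range(i):
            w -= (E[j] @ w) * E[j]
        nrm = np.linalg.norm(w)
        if nrm <= _DEP_TOL * np.linalg.norm(v):
            raise np.linalg.LinAlgError(
                f"derivative of order {i + 1} is linearly dependent on lower orders"
            )
        E[i] = w / nrm
    return FrenetFrame(E=E)


def _gram_volumes(vs: list[np.ndarray]) -> np.ndarray:
    """D_i = sqrt(det Gram(v_1..v_i)) for i = 0..k (D_0 = 1)."""
    M = np.column_stack(vs)
    k = M.shape[1]
    D = np.empty(k + 1)
    D[0] = 1.0
    for i in range(1, k + 1):
        G = M[:, :i].T @ M[:, :i]
        det = np.linalg.det(G)
        if not np.isfinite(det) or det <= 0.0:
            raise np.linalg.LinAlgError(
                f"Gram matrix of the first {i} derivatives is singular "
                "(linearly dependent derivatives; curvature undefined)"
            )
        D[i] = np.sqrt(det)
    return D


def gram_curvatures(derivs: list[np.ndarray]) -> CurvatureEstimate:
    """Exact curvatures from derivative vectors via Gram determinants.

    With k derivative vectors this yields ``kappa_1..kappa_{k-1}``; e.g.
    ``kappa_1 = sqrt(det Gram(g', g'')) / ||g'||^3`` reduces to the
    classical curvature of a space curve.  The independence tolerance is
    the same as for :func:`frenet_frame`.
    """
    if len(derivs) < 2:
        raise ValueError("need at least two derivative vectors")
    vs = [np.asarray(v, dtype=float) for v in derivs]
    # reject near-dependence early with a scale-aware check
    frenet_frame(vs)
    D = _gram_volumes(vs)
    speed = float(np.linalg.norm(vs[0]))
    k = len(vs)
    kappas = np.array(
        [D[i + 1] * D[i - 1] / (D[i] ** 2 * speed) for i in range(1, k)]
    )
    return CurvatureEstimate(kappas=kappas, speed=speed, K=curvature_matrix(kappas))


def curvature_matrix(kappas: np.ndarray) -> np.ndarray:
    """The antisymmetric tridiagonal curvature matrix built from kappas."""
    kappas = np.asarray(kappas, dtype=float)
    r = kappas.size + 1
    K = np.zeros((r, r))
    idx = np.arange(r - 1)
    K[idx, idx + 1] = kappas
    K[idx + 1, idx] = -kappas
    return K


def curvature_from_model(model: HavokModel, emb: DelayEmbedding) -> CurvatureEstimate:
    """Curvatures from a fitted model: ``K = A / ||h0'||``.

    The speed is the Euclidean norm of the finite-difference first
    derivative of the centre delay row; curvature magnitudes are read off
    the super-diagonal of K, which empirically tracks the true curvatures
    more closely than the sub-diagonal for plain HAVOK fits.
    """
    if not emb.centred or emb.h0 is None:
        raise ValueError("curvature extraction needs a centred embedding")
    h0p = fd_derivatives(emb.h0, emb.dt, 1)[0]
    speed = float(np.linalg.norm(h0p))
    K = model.A / speed
    kappas = np.abs(np.diag(K, 1))
    return CurvatureEstimate(kappas=kappas, speed=speed, K=K)


def structure_report(A: np.ndarray) -> StructureReport:
    """Antisymmetry / tridiagonality indices and spectral stability margin."""
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError("A must be square")
    if not np.all(np.isfinite(A)):
        raise ValueError("A contains non-finite entries")
    total = np.linalg.norm(A)
    if total == 0.0:
        anti = 0.0
        offband = 0.0
    else:
        anti = float(np.linalg.norm(A + A.T) / (2.0 * total))
        i, j = np.indices(A.shape)
        offband = float(np.sum(A[np.abs(i - j) >= 2] ** 2) / total**2)
    max_real = float(np.max(np.linalg.eigvals(A).real)) if A.size else 0.0
    return StructureReport(antisym_index=anti, tridiag_index=offband, max_real=max_real)
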
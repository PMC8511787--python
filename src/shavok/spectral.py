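"""Truncated SVD with fixed orientation/sign conventions, plus the discrete
orthogonal polynomial bases that the delay-direction singular vectors of a
centred Hankel matrix approximate.

Orientation convention
----------------------
The pipeline always decomposes the *transpose* of the (centred) Hankel
matrix: ``H^T = V S U^T`` with ``V`` of shape ``n x r`` (temporal
coordinates, the model state) and ``U`` of shape ``m x r`` (delay-direction
modes, which for centred data resemble odd-index-power orthogonal
polynomials and for uncentred data resemble discrete Legendre polynomials).
A deterministic sign canon — the largest-magnitude entry of each U column
is positive — removes the per-mode sign ambiguity of the SVD; when two
independently computed bases must be multiplied together, ``align_bases``
re-flips one of them so paired modes overlap positively.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg

__all__ = [
    "SpectralBasis",
    "PolynomialBasis",
    "truncated_svd",
    "default_rank",
    "align_bases",
    "discrete_polynomials",
    "polynomial_similarity",
]

_ORTHO_TOL = 1e-10


@dataclass(frozen=True)
class SpectralBasis:
    """Rank-r truncated SVD factors ``M = U diag(S) V^T`` (delay-space M)."""

    U: np.ndarray  # m x r, delay-direction modes
    S: np.ndarray  # r singular values, descending
    V: np.ndarray  # n x r, temporal coordinates
    r: int

    def __post_init__(self) -> None:
        if self.U.shape[1] != self.r or self.V.shape[1] != self.r:
            raise ValueError("factor column counts must equal r")
        if np.any(np.diff(self.S) > 0) or np.any(self.S < 0):
            raise ValueError("singular values must be non-negative and descending")


@dataclass(frozen=True)
class PolynomialBasis:
    """Discrete orthonormal polynomials in the centred index vector p.

    ``variant='centred'`` spans powers ``p, p^2, .., p^r`` (degrees 1..r, no
    constant term — the basis the centred pipeline produces); ``'legendre'``
    spans ``1, p, .., p^(r-1)`` (degrees 0..r-1, the uncentred analogue).
    """

    P: np.ndarray  # m x r, orthonormal columns
    variant: str
    p: np.ndarray  # the centred integer index vector


def truncated_svd(M: np.ndarray, r: int) -> SpectralBasis:
    """Rank-r SVD of delay-space matrix ``M`` (m x n) with the sign canon.

    Returns factors so that ``M ~ U diag(S) V^T`` with relative spectral
    error ``sigma_{r+1}/sigma_1``.  Sign flips are applied jointly to
    ``(U, V)`` column pairs, leaving the product unchanged.
    """
    M = np.asarray(M, dtype=float)
    if not np.all(np.isfinite(M)):
        raise ValueError("matrix contains non-finite entries")
    if r > min(M.shape):
        raise ValueError(f"rank {r} exceeds min(shape)={min(M.shape)}")
    if r < 1:
        raise ValueError("rank must be >= 1")
    # decompose the transpose so V (temporal) is the left factor
    W, s, Xt = linalg.svd(M.T, full_matrices=False)
    V = W[:, :r]
    S = s[:r].copy()
    U = Xt[:r].T.copy()
    V = V.copy()
    # sign canon: largest-|entry| of each U column positive
    for j in range(r):
        k = int(np.argmax(np.abs(U[:, j])))
        if U[k, j] < 0:
            U[:, j] = -U[:, j]
            V[:, j] = -V[:, j]
    return SpectralBasis(U=U, S=S, V=V, r=r)


def default_rank(M: np.ndarray, rel_tol: float = 1e-8) -> int:
    """Default truncation rank: number of singular values above ``rel_tol * sigma_1``."""
    s = linalg.svdvals(np.asarray(M, dtype=float))
    if s.size == 0 or s[0] == 0.0:
        return 0
    return int(np.count_nonzero(s > rel_tol * s[0]))


def align_bases(ref: SpectralBasis, other: SpectralBasis) -> SpectralBasis:
    """Sign-align ``other`` to ``ref`` so paired temporal modes overlap positively.

    Flips each (U, V) column pair of ``other`` so every diagonal entry of
    ``other.V^T @ ref.V`` is >= 0.  A near-zero diagonal overlap means the
    two decompositions' modes are not in one-to-one correspondence (e.g. a
    degenerate or reordered pair) and is an error.
    """
    if ref.r != other.r:
        raise ValueError("ranks differ")
    if ref.V.shape[0] != other.V.shape[0]:
        raise ValueError("temporal factor row counts differ")
    overlaps = np.einsum("ij,ij->j", other.V, ref.V)
    small = np.abs(overlaps) < 1e-6
    if np.any(small):
        bad = int(np.flatnonzero(small)[0])
        raise ValueError(
            f"modes not in correspondence: |overlap| of mode {bad + 1} is "
            f"{abs(overlaps[bad]):.2e}"
        )
    signs = np.sign(overlaps)
    return SpectralBasis(
        U=other.U * signs, S=other.S.copy(), V=other.V * signs, r=other.r
    )


def discrete_polynomials(m: int, r: int, variant: str = "centred") -> PolynomialBasis:
    """Orthonormal polynomial columns over the centred index grid.

    Gram-Schmidt (via QR with positive diagonal) applied, in order, to the
    element-wise powers of ``p = [-(m-1)/2, ..., 0, ..., (m-1)/2]``:
    ``{p, p^2, .., p^r}`` for the centred variant, ``{1, p, .., p^(r-1)}``
    for the Legendre variant.
    """
    if variant not in {"centred", "legendre"}:
        raise ValueError("variant must be 'centred' or 'legendre'")
    if variant == "centred" and m % 2 == 0:
        raise ValueError("centred variant needs odd m")
    if r > m or r < 1:
        raise ValueError("need 1 <= r <= m")
    p = np.arange(m, dtype=float) - (m - 1) / 2.0
    # scale to [-1, 1] before taking powers: same span, better conditioning
    ps = p / max((m - 1) / 2.0, 1.0)
    if variant == "centred":
        cols = [ps ** (k + 1) for k in range(r)]
    else:
        cols = [ps**k for k in range(r)]
    A = np.column_stack(cols)
    Q, R = np.linalg.qr(A)
    signs = np.sign(np.diag(R))
    signs[signs == 0] = 1.0
    Q = Q * signs
    return PolynomialBasis(P=Q, variant=variant, p=p)


def polynomial_similarity(B: SpectralBasis, P: PolynomialBasis) -> np.ndarray:
    """Per-mode |cosine| between U columns and the matching polynomial columns."""
    if B.U.shape[0] != P.P.shape[0]:
        raise ValueError("delay dimensions differ")
    r = min(B.r, P.P.shape[1])
    if B.r != P.P.shape[1]:
        raise ValueError("mode counts differ")
    scores = np.empty(r)
    for j in range(r):
        u, q = B.U[:, j], P.P[:, j]
        scores[j] = abs(float(u @ q)) / (np.linalg.norm(u) * np.linalg.norm(q))
    return scores
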
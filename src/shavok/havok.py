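"""HAVOK and structured-HAVOK (sHAVOK) linear models of delay coordinates.

Both methods regress linear continuous-time dynamics ``v'(t) = A v(t)``
(optionally plus a scalar forcing in the last retained coordinate,
``v'(t) = A v(t) + B v_r(t)``) on the temporal singular coordinates of a
time-delay Hankel matrix:

* HAVOK takes a single rank-r SVD of the (centred) Hankel matrix and
  regresses the time-shifted slices of its temporal factor ``V`` on each
  other.  The slices are *not* orthogonal, which blurs the antisymmetric
  tridiagonal structure predicted by the Frenet-Serret correspondence when
  data are short or noisy.
* sHAVOK instead splits the Hankel matrix itself into two column-shifted
  copies and takes two independent rank-r SVDs, so both coordinate bases
  are exactly orthonormal; the discrete map is then simply ``V2^T V1`` and
  the continuous model ``A = (V2^T V1 - I)/dt``.  This promotes the
  antisymmetric structure, recovering curvature estimates accurate to
  several decimals from the same data.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .embedding import DelayEmbedding, split_pair
from .signals import TimeSeries
from .spectral import SpectralBasis, align_bases, truncated_svd

__all__ = [
    "HavokModel",
    "ModelSpectrum",
    "fit_havok",
    "fit_shavok",
    "continuousize",
    "spectrum",
    "simulate_model",
    "reconstruct_signal",
    "estimate_forcing",
    "save_model",
    "load_model",
]

_COND_LIMIT = 1e12
_PINV_RCOND = 1e-12


@dataclass(frozen=True)
class HavokModel:
    """A fitted continuous-time linear delay-coordinate model.

    ``A`` is d x d with d = r (closed) or r - 1 (forced); ``B`` is the
    length-d forcing vector (forced models only), multiplying the scalar
    r-th coordinate.  ``basis`` retains the lifting SVD factors and ``h0``
    the centre delay row (centred models), enabling signal reconstruction.
    """

    A: np.ndarray
    B: np.ndarray | None
    r: int
    dt: float
    variant: str  # "havok" | "shavok"
    centred: bool
    closed: bool
    basis: SpectralBasis | None = None
    h0: np.ndarray | None = None

    def __post_init__(self) -> None:
        d = self.r if self.closed else self.r - 1
        if self.A.shape != (d, d):
            raise ValueError(f"A must be {d}x{d} for r={self.r}, closed={self.closed}")
        if self.closed and self.B is not None:
            raise ValueError("closed model must not carry a forcing vector")
        if not self.closed and (self.B is None or self.B.shape != (d,)):
            raise ValueError("forced model needs a length-(r-1) forcing vector")
        if self.variant not in {"havok", "shavok"}:
            raise ValueError("variant must be 'havok' or 'shavok'")

    @property
    def d(self) -> int:
        """State dimension: r when closed, r - 1 when forced."""
        return self.r if self.closed else self.r - 1


@dataclass(frozen=True)
class ModelSpectrum:
    """Continuous-time eigenvalues of a fitted model."""

    omegas: np.ndarray
    max_real: float


def _check_conditioning(V1: np.ndarray) -> None:
    s = np.linalg.svd(V1, compute_uv=False)
    if s[-1] == 0.0 or s[0] / s[-1] > _COND_LIMIT:
        bad = int(np.argmin(s)) + 1
        raise np.linalg.LinAlgError(
            f"regressor matrix is rank deficient (condition > {_COND_LIMIT:.0e}); "
            f"mode {bad} carries no independent information — reduce r"
        )


def _check_rank(basis: SpectralBasis) -> None:
    # a numerically zero singular value means the requested rank exceeds the
    # information in the data (e.g. a constant series after centring)
    s = basis.S
    if s[0] == 0.0 or s[-1] < 1e-14 * s[0]:
        bad = int(np.argmin(s)) + 1
        raise np.linalg.LinAlgError(
            f"Hankel matrix is rank deficient at the requested truncation; "
            f"mode {bad} has a numerically zero singular value"
        )


def continuousize(
    Ahat: np.ndarray, Bhat: np.ndarray | None, dt: float
) -> tuple[np.ndarray, np.ndarray | None]:
    """First-order discrete-to-continuous conversion.

    ``A = (Ahat - I)/dt`` and, for the forcing vector, ``B = Bhat/dt``
    (the vector has no identity to subtract).
    """
    if not (dt > 0):
        raise ValueError("dt must be > 0")
    A = (Ahat - np.eye(Ahat.shape[0])) / dt
    B = None if Bhat is None else Bhat / dt
    return A, B


def fit_havok(emb: DelayEmbedding, r: int, closed: bool = False) -> HavokModel:
    """Fit a HAVOK model: one SVD, shifted-V least-squares regression.

    The temporal factor ``V`` (n x r) is sliced into ``V1 = V[:-1]`` and
    ``V2 = V[1:]``; the discrete map ``Ahat = V2^T (V1^T)^+`` is converted
    to continuous time at first order.  Forced models regress the first
    r - 1 coordinates on all r, so the r-th coordinate acts as a scalar
    exogenous forcing.
    """
    if emb.n < r + 1:
        raise ValueError("need at least r + 1 Hankel columns")
    basis = truncated_svd(emb.H, r)
    _check_rank(basis)
    V = basis.V
    V1 = V[:-1]
    V2 = V[1:]
    _check_conditioning(V1)
    pinv_V1 = np.linalg.pinv(V1, rcond=_PINV_RCOND)
    if closed:
        Ahat = (pinv_V1 @ V2).T
        A, B = continuousize(Ahat, None, emb.dt)
    else:
        if r < 2:
            raise ValueError("forced model needs r >= 2")
        AB = (pinv_V1 @ V2[:, : r - 1]).T  # (r-1) x r
        A, B = continuousize(AB[:, : r - 1], AB[:, r - 1], emb.dt)
    return HavokModel(
        A=A, B=B, r=r, dt=emb.dt, variant="havok", centred=emb.centred,
        closed=closed, basis=basis, h0=None if emb.h0 is None else emb.h0.copy(),
    )


def fit_shavok(emb: DelayEmbedding, r: int, closed: bool = False) -> HavokModel:
    """Fit a structured HAVOK model: two SVDs of column-shifted Hankel halves.

    The embedding is split into ``H1 = H[:, :-1]`` and ``H2 = H[:, 1:]``,
    each decomposed at rank r; the second basis is sign-aligned to the
    first so the product ``V2^T V1`` is well defined, and
    ``A = (V2^T V1 - I)/dt``.  Both coordinate bases are orthonormal by
    construction, which is what promotes the antisymmetric tridiagonal
    structure.  State and lifting use the ``H1`` basis.
    """
    if emb.n < r + 1:
        raise ValueError("need at least r + 1 Hankel columns")
    pair = split_pair(emb)
    b1 = truncated_svd(pair.H1, r)
    _check_rank(b1)
    b2 = align_bases(b1, truncated_svd(pair.H2, r))
    _check_conditioning(b1.V)
    prod = b2.V.T @ b1.V  # r x r, both factors orthonormal
    if closed:
        A, B = continuousize(prod, None, emb.dt)
    else:
        if r < 2:
            raise ValueError("forced model needs r >= 2")
        AB = prod[: r - 1, :]  # (r-1) x r
        A, B = continuousize(AB[:, : r - 1], AB[:, r - 1], emb.dt)
    return HavokModel(
        A=A, B=B, r=r, dt=emb.dt, variant="shavok", centred=emb.centred,
        closed=closed, basis=b1, h0=None if emb.h0 is None else emb.h0.copy(),
    )


def spectrum(model: HavokModel, path: str = "continuous") -> ModelSpectrum:
    """Continuous-time eigenvalues of the fitted dynamics.

    ``path='continuous'`` takes eigenvalues of A directly;
    ``path='discrete_log'`` maps through the discrete operator,
    ``omega = log(eig(I + dt*A))/dt``, which differs at second order in dt.
    """
    if path == "continuous":
        w = np.linalg.eigvals(model.A)
    elif path == "discrete_log":
        lam = np.linalg.eigvals(np.eye(model.d) + model.dt * model.A)
        w = np.log(lam.astype(complex)) / model.dt
    else:
        raise ValueError("path must be 'continuous' or 'discrete_log'")
    return ModelSpectrum(omegas=w, max_real=float(np.max(w.real)))


def simulate_model(
    model: HavokModel,
    v0: np.ndarray,
    forcing: np.ndarray | None = None,
    steps: int = 1,
) -> np.ndarray:
    """Integrate ``v' = A v (+ B v_r)`` with fixed-step RK4 at the model dt.

    The forcing sample for each step is held constant over that step
    (zero-order hold).  Returns a ``steps x d`` trajectory whose first row
    is ``v0``.
    """
    v0 = np.asarray(v0, dtype=float)
    if v0.shape != (model.d,):
        raise ValueError(f"v0 must have length d={model.d}")
    if not model.closed:
        if forcing is None:
            raise ValueError("forced model requires a forcing series")
        forcing = np.asarray(forcing, dtype=float)
        if forcing.size < steps:
            raise ValueError("forcing series shorter than requested steps")
    A, B, dt = model.A, model.B, model.dt
    out = np.empty((steps, model.d))
    out[0] = v0
    v = v0
    for k in range(1, steps):
        u = 0.0 if model.closed else forcing[k - 1]
        drive = 0.0 if model.closed else B * u

        def f(y: np.ndarray) -> np.ndarray:
            return A @ y + drive

        k1 = f(v)
        k2 = f(v + 0.5 * dt * k1)
        k3 = f(v + 0.5 * dt * k2)
        k4 = f(v + dt * k3)
        v = v + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        out[k] = v
    return out


def reconstruct_signal(model: HavokModel, traj: np.ndarray) -> TimeSeries:
    """Lift a state trajectory back to the scalar signal.

    Rebuilds the centre delay row of the Hankel matrix as
    ``U[c, :d] @ (S[:d] * v(t))`` and, for centred models, adds the stored
    centre row ``h0`` back (the trajectory must then fit inside it).
    """
    if model.basis is None:
        raise ValueError("model does not retain its lifting basis")
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    if traj.shape[1] != model.d:
        raise ValueError(f"trajectory state dimension must be {model.d}")
    m = model.basis.U.shape[0]
    if m % 2 == 0:
        c = m // 2
    else:
        c = (m - 1) // 2
    lift = model.basis.U[c, : model.d] * model.basis.S[: model.d]
    x = traj @ lift
    if model.centred:
        if model.h0 is None:
            raise ValueError("centred model without stored h0")
        if traj.shape[0] > model.h0.size:
            raise ValueError("trajectory longer than the stored centre row")
        x = x + model.h0[: traj.shape[0]]
    return TimeSeries(x, dt=model.dt)


def estimate_forcing(model: HavokModel, window: np.ndarray) -> float:
    """Forcing coordinate ``v_r`` from one length-m delay window.

    Projects the (centred) window on the r-th delay-direction mode scaled
    by the inverse r-th singular value.  For centred models the window's
    middle sample is subtracted first, mirroring the training centring.
    """
    if model.closed:
        raise ValueError("closed models have no forcing coordinate")
    if model.basis is None:
        raise ValueError("model does not retain its lifting basis")
    window = np.asarray(window, dtype=float)
    m = model.basis.U.shape[0]
    if window.shape != (m,):
        raise ValueError(f"window must have length m={m}")
    if model.centred:
        window = window - window[(m - 1) // 2]
    return float(model.basis.U[:, model.r - 1] @ window / model.basis.S[model.r - 1])


def project_window(model: HavokModel, window: np.ndarray) -> np.ndarray:
    """All d state coordinates of one delay window (same centring rule)."""
    if model.basis is None:
        raise ValueError("model does not retain its lifting basis")
    window = np.asarray(window, dtype=float)
    m = model.basis.U.shape[0]
    if window.shape != (m,):
        raise ValueError(f"window must have length m={m}")
    if model.centred:
        window = window - window[(m - 1) // 2]
    return (model.basis.U[:, : model.d].T @ window) / model.basis.S[: model.d]


def save_model(model: HavokModel, path: str) -> None:
    """Serialize to a JSON document plus a companion dense-matrix CSV.

    The JSON holds A, B, the singular values, dt, r, variant and flags;
    the companion ``<stem>.basis.csv`` holds the delay-direction modes U
    (one column per mode) and, for centred models, ``<stem>.h0.csv`` the
    centre row.  The temporal factor V is not persisted.
    """
    stem = os.path.splitext(path)[0]
    doc = {
        "A": model.A.tolist(),
        "B": None if model.B is None else model.B.tolist(),
        "S": None if model.basis is None else model.basis.S.tolist(),
        "dt": model.dt,
        "r": model.r,
        "variant": model.variant,
        "centred": model.centred,
        "closed": model.closed,
        "has_basis": model.basis is not None,
        "has_h0": model.h0 is not None,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
    if model.basis is not None:
        np.savetxt(stem + ".basis.csv", model.basis.U, delimiter=",", fmt="%.17g")
    if model.h0 is not None:
        np.savetxt(stem + ".h0.csv", model.h0, delimiter=",", fmt="%.17g")


def load_model(path: str) -> HavokModel:
    """Load a serialized model, validating shapes and orthonormality."""
    stem = os.path.splitext(path)[0]
    with open(path) as fh:
        doc = json.load(fh)
    A = np.asarray(doc["A"], dtype=float)
    B = None if doc["B"] is None else np.asarray(doc["B"], dtype=float)
    basis = None
    if doc["has_basis"]:
        U = np.loadtxt(stem + ".basis.csv", delimiter=",", ndmin=2)
        S = np.asarray(doc["S"], dtype=float)
        if U.shape[1] != doc["r"]:
            raise ValueError("basis column count does not match r")
        if np.linalg.norm(U.T @ U - np.eye(doc["r"])) > 1e-8:
            raise ValueError("stored delay modes are not orthonormal")
        # V was not persisted; store an empty temporal factor
        basis = SpectralBasis(U=U, S=S, V=np.empty((0, doc["r"])), r=doc["r"])
    h0 = None
    if doc["has_h0"]:
        h0 = np.loadtxt(stem + ".h0.csv", delimiter=",")
    return HavokModel(
        A=A, B=B, r=doc["r"], dt=doc["dt"], variant=doc["variant"],
        centred=doc["centred"], closed=doc["closed"], basis=basis, h0=h0,
    )
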
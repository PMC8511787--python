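"""Deterministic generators for the synthetic study systems.

Provides the closed-form two-tone sinusoid worked example (with analytic
derivative vectors for the centre delay row, used as the curvature oracle
input) and fixed-step RK4 simulators for the Lorenz system, the Roessler
system and a frictionless point-mass double pendulum.  All generators are
deterministic: identical specifications produce bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .signals import TimeSeries

__all__ = [
    "SimulatorSpec",
    "MultiSeries",
    "SinusoidExample",
    "sinusoid_example",
    "simulate_lorenz",
    "simulate_rossler",
    "simulate_double_pendulum",
    "simulate_system",
    "double_pendulum_energy",
    "LORENZ_DEFAULTS",
    "ROSSLER_DEFAULTS",
    "PENDULUM_DEFAULTS",
]

LORENZ_DEFAULTS = {"sigma": 10.0, "rho": 28.0, "beta": 8.0 / 3.0}
ROSSLER_DEFAULTS = {"a": 0.1, "b": 0.1, "c": 14.0}
PENDULUM_DEFAULTS = {"m": 1.0, "l": 1.0, "g": 10.0}

_REQUIRED_PARAMS = {
    "lorenz": ("sigma", "rho", "beta"),
    "rossler": ("a", "b", "c"),
    "double_pendulum": ("m", "l", "g"),
}
_STATE_DIM = {"lorenz": 3, "rossler": 3, "double_pendulum": 4}


@dataclass(frozen=True)
class SimulatorSpec:
    """Full description of one simulation run."""

    system: str
    init: tuple
    dt: float
    steps: int
    params: dict = field(default_factory=dict)
    observable: int | str = 0

    def __post_init__(self) -> None:
        if self.system not in _REQUIRED_PARAMS and self.system != "sinusoid":
            raise ValueError(
                f"unknown system {self.system!r}; valid: sinusoid, "
                + ", ".join(_REQUIRED_PARAMS)
            )
        if not (self.dt > 0):
            raise ValueError("dt must be > 0")
        if self.steps < 2:
            raise ValueError("steps must be >= 2")
        if self.system in _REQUIRED_PARAMS:
            missing = [k for k in _REQUIRED_PARAMS[self.system] if k not in self.params]
            if missing:
                raise ValueError(f"missing parameters for {self.system}: {missing}")
            if len(self.init) != _STATE_DIM[self.system]:
                raise ValueError(
                    f"{self.system} needs a {_STATE_DIM[self.system]}-component "
                    "initial state"
                )


@dataclass(frozen=True)
class MultiSeries:
    """A steps x k matrix of simulated states on a uniform grid."""

    states: np.ndarray
    dt: float
    t0: float = 0.0

    def observable(self, index: int = 0, transform: Callable | None = None) -> TimeSeries:
        """Extract one state coordinate (optionally transformed) as a series."""
        col = np.asarray(self.states[:, index], dtype=float)
        if transform is not None:
            col = transform(col)
        return TimeSeries(col, dt=self.dt, t0=self.t0)


def _rk4(f: Callable, y0: np.ndarray, dt: float, steps: int) -> np.ndarray:
    y = np.asarray(y0, dtype=float)
    out = np.empty((steps, y.size))
    out[0] = y
    for k in range(1, steps):
        k1 = f(y)
        k2 = f(y + 0.5 * dt * k1)
        k3 = f(y + 0.5 * dt * k2)
        k4 = f(y + dt * k3)
        y = y + (dt / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        out[k] = y
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("integration produced non-finite state")
    return out


@dataclass(frozen=True)
class SinusoidExample:
    """The two-tone worked example x(t) = sin t + sin 2t with exact derivatives."""

    series: TimeSeries

    def centre_grid(self, m: int) -> np.ndarray:
        """Times of the middle delay row for an m-row Hankel embedding."""
        if m % 2 == 0:
            raise ValueError("centre grid needs odd m")
        dt = self.series.dt
        q = len(self.series)
        half = (m - 1) // 2
        return self.series.t0 + dt * np.arange(half, q - half)

    def derivative(self, order: int, m: int) -> np.ndarray:
        """Exact order-k derivative of the centre row, sampled on centre_grid(m).

        Order 0 is the signal itself.  Because x solves
        x'''' + 5 x'' + 4 x = 0, every derivative is a combination of the
        first four; they are produced in closed form for any order.
        """
        t = self.centre_grid(m)
        # d^k sin(wt) cycles with period 4 in k
        def dsin(w: float, k: int) -> np.ndarray:
            phase = k % 4
            s = w**k
            return s * [np.sin, np.cos, lambda u: -np.sin(u), lambda u: -np.cos(u)][
                phase
            ](w * t)

        return dsin(1.0, order) + dsin(2.0, order)


def sinusoid_example(dt: float = 0.001, t_end: float = 10.0) -> SinusoidExample:
    """Sample x(t) = sin t + sin 2t on [0, t_end] at period dt."""
    if not (dt > 0):
        raise ValueError("dt must be > 0")
    n = int(round(t_end / dt)) + 1
    t = dt * np.arange(n)
    return SinusoidExample(TimeSeries(np.sin(t) + np.sin(2 * t), dt=dt, t0=0.0))


def simulate_lorenz(spec: SimulatorSpec) -> MultiSeries:
    """Fixed-step RK4 for the Lorenz-63 system (state x, y, z)."""
    p = spec.params
    sig, rho, beta = p["sigma"], p["rho"], p["beta"]

    def f(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([sig * (y - x), x * (rho - z) - y, x * y - beta * z])

    return MultiSeries(_rk4(f, np.asarray(spec.init), spec.dt, spec.steps), dt=spec.dt)


def simulate_rossler(spec: SimulatorSpec) -> MultiSeries:
    """Fixed-step RK4 for the Roessler system (state x, y, z)."""
    p = spec.params
    a, b, c = p["a"], p["b"], p["c"]

    def f(s: np.ndarray) -> np.ndarray:
        x, y, z = s
        return np.array([-y - z, x + a * y, b + z * (x - c)])

    return MultiSeries(_rk4(f, np.asarray(spec.init), spec.dt, spec.steps), dt=spec.dt)


def simulate_double_pendulum(spec: SimulatorSpec) -> MultiSeries:
    """Fixed-step RK4 for a frictionless planar double pendulum.

    Point masses m at the end of each massless rod of length l; state is
    (theta1, theta2, dtheta1, dtheta2) with angles measured from vertical.
    The equations of motion follow from the Lagrangian
    ``L = (m l^2 / 6)(th2'^2 + 4 th1'^2 + 3 th1' th2' cos(th1 - th2))
    + (m g l / 2)(3 cos th1 + cos th2)`` via the Euler-Lagrange equations:

        8 th1'' + 3 cos(D) th2'' = -3 sin(D) th2'^2 - 9 (g/l) sin th1
        3 cos(D) th1'' + 2 th2'' =  3 sin(D) th1'^2 - 3 (g/l) sin th2

    with D = th1 - th2.  The conventional observable is sin(theta1).
    """
    p = spec.params
    g_over_l = p["g"] / p["l"]

    def f(s: np.ndarray) -> np.ndarray:
        th1, th2, w1, w2 = s
        d = th1 - th2
        c, sn = np.cos(d), np.sin(d)
        rhs1 = -3.0 * sn * w2**2 - 9.0 * g_over_l * np.sin(th1)
        rhs2 = 3.0 * sn * w1**2 - 3.0 * g_over_l * np.sin(th2)
        det = 16.0 - 9.0 * c * c
        a1 = (2.0 * rhs1 - 3.0 * c * rhs2) / det
        a2 = (8.0 * rhs2 - 3.0 * c * rhs1) / det
        return np.array([w1, w2, a1, a2])

    return MultiSeries(_rk4(f, np.asarray(spec.init), spec.dt, spec.steps), dt=spec.dt)


def double_pendulum_energy(states: np.ndarray, m: float, l: float, g: float) -> np.ndarray:
    """Total energy along a double-pendulum trajectory (conservation check)."""
    th1, th2, w1, w2 = states.T
    kin = (m * l * l / 6.0) * (w2**2 + 4.0 * w1**2 + 3.0 * w1 * w2 * np.cos(th1 - th2))
    pot = -(m * g * l / 2.0) * (3.0 * np.cos(th1) + np.cos(th2))
    return kin + pot


_DISPATCH = {
    "lorenz": simulate_lorenz,
    "rossler": simulate_rossler,
    "double_pendulum": simulate_double_pendulum,
}


def simulate_system(spec: SimulatorSpec) -> MultiSeries:
    """Dispatch to the named simulator."""
    if spec.system not in _DISPATCH:
        raise ValueError(
            f"unknown system {spec.system!r}; valid: " + ", ".join(_DISPATCH)
        )
    return _DISPATCH[spec.system](spec)
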
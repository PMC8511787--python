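"""Shared fixtures: the two-tone worked example and Lorenz window suites.

The expensive objects (10k-sample sinusoid embedding, its SVD models, the
60k-sample Lorenz trajectory) are session-scoped so each is built once.
"""

from __future__ import annotations

import numpy as np
import pytest

import shavok as sh

SIN_DT = 0.001
SIN_T_END = 10.0
SIN_M = 41
SIN_R = 4


@pytest.fixture(scope="session")
def sin_ex() -> sh.SinusoidExample:
    """x(t) = sin t + sin 2t on [0, 10] at dt = 0.001 (q = 10001)."""
    return sh.sinusoid_example(SIN_DT, SIN_T_END)


@pytest.fixture(scope="session")
def sin_emb(sin_ex) -> sh.DelayEmbedding:
    """Centred 41-row Hankel embedding of the worked example."""
    return sh.centre(sh.build_hankel(sin_ex.series, SIN_M))


@pytest.fixture(scope="session")
def sin_derivs(sin_ex) -> list[np.ndarray]:
    """Analytic derivative vectors of the centre row, orders 1-4."""
    return [sin_ex.derivative(k, SIN_M) for k in (1, 2, 3, 4)]


@pytest.fixture(scope="session")
def havok_model(sin_emb) -> sh.HavokModel:
    return sh.fit_havok(sin_emb, SIN_R, closed=True)


@pytest.fixture(scope="session")
def shavok_model(sin_emb) -> sh.HavokModel:
    return sh.fit_shavok(sin_emb, SIN_R, closed=True)


@pytest.fixture(scope="session")
def lorenz_x() -> np.ndarray:
    """x-coordinate of a 60-time-unit Lorenz run at dt = 0.001."""
    spec = sh.SimulatorSpec(
        "lorenz", init=(-8.0, 8.0, 27.0), dt=0.001, steps=60000,
        params=sh.LORENZ_DEFAULTS,
    )
    return sh.simulate_lorenz(spec).observable(0).values


def lorenz_window_suite(lorenz_x, n_windows=20, seed=12345, noise=0.0):
    """Random 3000-sample windows of the long trajectory, optional noise."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_windows):
        start = int(rng.integers(5000, lorenz_x.size - 3000))
        seg = lorenz_x[start : start + 3000].copy()
        if noise:
            seg = seg + rng.normal(0.0, noise * np.std(seg), seg.size)
        out.append(sh.TimeSeries(seg, dt=0.001))
    return out


def lorenz_ic_suite(n_runs=20, seed=12345, noise=0.01):
    """Fresh 3000-sample simulations from perturbed initial conditions.

    Initial states are [-8, 8, 27] + N(0, 1) perturbations; measurement
    noise is Gaussian at ``noise`` times the signal RMS.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_runs):
        ic = np.array([-8.0, 8.0, 27.0]) + rng.normal(0.0, 1.0, 3)
        spec = sh.SimulatorSpec(
            "lorenz", init=tuple(ic), dt=0.001, steps=3000,
            params=sh.LORENZ_DEFAULTS,
        )
        seg = sh.simulate_lorenz(spec).observable(0).values.copy()
        if noise:
            seg = seg + rng.normal(0.0, noise * np.std(seg), seg.size)
        out.append(sh.TimeSeries(seg, dt=0.001))
    return out
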
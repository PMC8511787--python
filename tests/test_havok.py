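"""HAVOK / sHAVOK fitting, spectra, simulation, lifting and serialization."""

import numpy as np
import pytest

import shavok as sh

# reference magnitudes of the worked-example curvature-scale matrix entries
# for the single-SVD (HAVOK) and split-SVD (sHAVOK) fits
HAVOK_SUPER = [1.205e-2, 4.458e-3, 6.617e-3]
SHAVOK_SUPER = [1.204e-2, 4.458e-3, 6.617e-3]


class TestFitHavok:
    def test_worked_example_superdiagonal(self, havok_model, sin_emb):
        est = sh.curvature_from_model(havok_model, sin_emb)
        K = est.K
        assert K.shape == (4, 4)
        assert np.allclose(np.abs(np.diag(K, 1)), HAVOK_SUPER, rtol=2e-3)

    def test_pure_sine_generator_spectrum(self):
        # two eigen-time-delay coordinates of sin t span {sin, cos}: the
        # exact generator has spectrum +-1i
        t = 0.001 * np.arange(10001)
        emb = sh.centre(sh.build_hankel(sh.TimeSeries(np.sin(t), dt=0.001), 41))
        model = sh.fit_havok(emb, 2, closed=True)
        w = np.sort_complex(np.linalg.eigvals(model.A))
        assert np.abs(w.imag)[0] == pytest.approx(1.0, rel=1e-3)
        assert np.all(np.abs(w.real) < 1e-3)

    def test_constant_signal_rank_deficient(self):
        emb = sh.centre(sh.build_hankel(sh.TimeSeries(np.full(101, 5.0), dt=0.1), 11))
        with pytest.raises(np.linalg.LinAlgError):
            sh.fit_havok(emb, 3, closed=True)

    def test_forced_shapes(self, sin_emb):
        model = sh.fit_havok(sin_emb, 4, closed=False)
        assert model.d == 3
        assert model.A.shape == (3, 3)
        assert model.B.shape == (3,)
        assert np.any(model.B != 0.0)


class TestFitShavok:
    def test_worked_example_pairwise_symmetric_diagonals(self, shavok_model, sin_emb):
        est = sh.curvature_from_model(shavok_model, sin_emb)
        K = est.K
        sup = np.abs(np.diag(K, 1))
        sub = np.abs(np.diag(K, -1))
        assert np.allclose(sup, SHAVOK_SUPER, rtol=2e-3)
        # split-SVD fit makes the two off-diagonals equal to high precision
        assert np.allclose(sup, sub, rtol=1e-4)

    def test_matches_analytic_curvatures_to_three_decimals(
        self, shavok_model, sin_emb, sin_derivs
    ):
        fitted = sh.curvature_from_model(shavok_model, sin_emb).kappas
        exact = sh.gram_curvatures(sin_derivs).kappas
        assert np.all(np.abs(fitted - exact) < 5e-4)

    def test_off_tridiagonal_mass_below_havok(self, havok_model, shavok_model):
        rh = sh.structure_report(havok_model.A)
        rs = sh.structure_report(shavok_model.A)
        assert rs.tridiag_index * 5.0 < rh.tridiag_index

    def test_long_data_convergence_to_havok(self):
        ex = sh.sinusoid_example(0.001, 100.0)
        emb = sh.centre(sh.build_hankel(ex.series, 41))
        A1 = sh.fit_havok(emb, 4, closed=True).A
        A2 = sh.fit_shavok(emb, 4, closed=True).A
        assert np.linalg.norm(A1 - A2) / np.linalg.norm(A1) < 1e-2


class TestContinuousize:
    def test_arithmetic(self):
        A, B = sh.continuousize(np.eye(3), None, 0.5)
        assert np.all(A == 0.0) and B is None
        G = np.array([[0.0, 1.0], [-1.0, 0.0]])
        A, _ = sh.continuousize(np.eye(2) + 0.01 * G, None, 0.01)
        assert np.allclose(A, G)
        _, B = sh.continuousize(np.eye(2), np.zeros(2), 0.1)
        assert np.all(B == 0.0)


class TestSpectrum:
    def test_zero_matrix(self):
        model = sh.HavokModel(
            A=np.zeros((3, 3)), B=None, r=3, dt=0.1, variant="havok",
            centred=False, closed=True,
        )
        sp = sh.spectrum(model)
        assert np.allclose(sp.omegas, 0.0)

    def test_antisymmetric_matrix_is_marginal(self):
        K = sh.curvature_matrix(np.array([1.0, 0.4]))
        model = sh.HavokModel(
            A=K, B=None, r=3, dt=0.01, variant="shavok", centred=False, closed=True
        )
        assert sh.spectrum(model).max_real < 1e-10

    def test_worked_fixture_frequency_ratio(self, havok_model):
        sp = sh.spectrum(havok_model, "discrete_log")
        mags = np.sort(np.abs(sp.omegas.imag))
        assert mags[-1] / mags[0] == pytest.approx(2.0, rel=1e-2)
        # conjugate closure for a real matrix
        assert np.allclose(
            np.sort_complex(sp.omegas), np.sort_complex(sp.omegas.conj()), atol=1e-10
        )


class TestSimulateModel:
    def _closed(self, A, dt=0.001):
        return sh.HavokModel(
            A=A, B=None, r=A.shape[0], dt=dt, variant="shavok",
            centred=False, closed=True,
        )

    def test_zero_dynamics_constant(self):
        traj = sh.simulate_model(self._closed(np.zeros((2, 2))), [1.0, -2.0], steps=50)
        assert np.all(traj == [1.0, -2.0])

    def test_antisymmetric_norm_conservation(self):
        model = self._closed(sh.curvature_matrix(np.array([2.0, 0.7, 1.1])))
        traj = sh.simulate_model(model, np.array([1.0, 0.0, 0.0, 0.5]), steps=10_000)
        norms = np.linalg.norm(traj, axis=1)
        assert np.max(np.abs(norms - norms[0])) < 1e-8

    def test_self_consistency_on_training_coordinates(self, havok_model):
        V = havok_model.basis.V
        traj = sh.simulate_model(havok_model, V[0], steps=V.shape[0])
        resid = np.sum((traj[:, 0] - V[:, 0]) ** 2)
        total = np.sum((V[:, 0] - V[:, 0].mean()) ** 2)
        assert 1 - resid / total > 0.99

    def test_forced_model_requires_forcing(self, sin_emb):
        model = sh.fit_havok(sin_emb, 4, closed=False)
        with pytest.raises(ValueError):
            sh.simulate_model(model, np.zeros(3), steps=10)
        with pytest.raises(ValueError):
            sh.simulate_model(model, np.zeros(3), forcing=np.zeros(5), steps=10)


class TestReconstructSignal:
    def test_training_coordinates_recover_centre_segment(self, havok_model, sin_ex, sin_emb):
        rec = sh.reconstruct_signal(havok_model, havok_model.basis.V)
        centre_seg = sin_ex.series.values[20 : 20 + sin_emb.n]
        s = np.linalg.svd(sin_emb.H, compute_uv=False)
        bound = (s[4] / s[0]) * np.max(np.abs(centre_seg)) + 1e-12
        assert np.max(np.abs(rec.values - centre_seg)) <= max(bound, 1e-10)

    def test_zero_trajectory_returns_h0(self, havok_model, sin_emb):
        rec = sh.reconstruct_signal(havok_model, np.zeros((100, 4)))
        assert np.allclose(rec.values, sin_emb.h0[:100])

    def test_unstable_model_diverges(self):
        # uncentred lift with an unstable generator grows exponentially
        t = 0.01 * np.arange(2000)
        emb = sh.build_hankel(sh.TimeSeries(np.sin(t) + 0.5 * np.sin(3 * t), dt=0.01), 21)
        model = sh.fit_havok(emb, 4, closed=True)
        unstable = sh.HavokModel(
            A=model.A + 0.5 * np.eye(4), B=None, r=4, dt=model.dt,
            variant="havok", centred=False, closed=True, basis=model.basis,
        )
        v0 = model.basis.V[0]
        traj = sh.simulate_model(unstable, v0, steps=3000)
        rec = sh.reconstruct_signal(unstable, traj)
        assert np.max(np.abs(rec.values[-100:])) > 100 * np.max(np.abs(rec.values[:100]))

    def test_missing_basis_rejected(self):
        model = sh.HavokModel(
            A=np.zeros((2, 2)), B=None, r=2, dt=0.1, variant="havok",
            centred=False, closed=True,
        )
        with pytest.raises(ValueError):
            sh.reconstruct_signal(model, np.zeros((5, 2)))


class TestEstimateForcing:
    def test_training_window_matches_stored_coordinate(self, sin_emb):
        model = sh.fit_havok(sin_emb, 4, closed=False)
        b = sh.truncated_svd(sin_emb.H, 4)
        j = 1234
        # uncentred window from the raw signal: column j of the raw Hankel
        window = sin_emb.H[:, j] + sin_emb.h0[j]
        assert sh.estimate_forcing(model, window) == pytest.approx(
            b.V[j, 3], abs=1e-8
        )

    def test_flat_window_gives_zero(self, sin_emb):
        model = sh.fit_havok(sin_emb, 4, closed=False)
        assert sh.estimate_forcing(model, np.full(41, 2.5)) == 0.0

    def test_wrong_length_rejected(self, sin_emb):
        model = sh.fit_havok(sin_emb, 4, closed=False)
        with pytest.raises(ValueError):
            sh.estimate_forcing(model, np.zeros(40))


class TestSerialization:
    def test_roundtrip(self, tmp_path, shavok_model):
        path = str(tmp_path / "model.json")
        sh.save_model(shavok_model, path)
        back = sh.load_model(path)
        assert np.allclose(back.A, shavok_model.A)
        assert back.variant == "shavok" and back.closed and back.r == 4
        assert np.allclose(back.basis.U, shavok_model.basis.U)
        assert np.allclose(back.h0, shavok_model.h0)

    def test_corrupt_basis_rejected(self, tmp_path, shavok_model):
        path = str(tmp_path / "model.json")
        sh.save_model(shavok_model, path)
        U = np.loadtxt(str(tmp_path / "model.basis.csv"), delimiter=",")
        U[:, 0] *= 2.0
        np.savetxt(str(tmp_path / "model.basis.csv"), U, delimiter=",")
        with pytest.raises(ValueError, match="orthonormal"):
            sh.load_model(path)
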
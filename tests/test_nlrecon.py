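import numpy as np
import pytest

from mbqmri import nlrecon as nl
from mbqmri._dictvec import dzeros_like
from mbqmri.data import KSpaceData
from mbqmri.encoding import ParamOperator
from mbqmri.signal_models import IRFlashModel, SpinEchoModel, TimeGrid
from mbqmri.trajectories import Trajectory


def dense_frame_traj(N, T):
    """Fully sampled Cartesian frequencies repeated for each frame."""
    kx, ky = np.meshgrid(np.arange(N) - N / 2, np.arange(N) - N / 2,
                         indexing="ij")
    coords = np.stack([kx, ky], -1).reshape(1, 1, -1, 2).repeat(T, 0)
    return Trajectory(coords, np.zeros((T, 1)), kmax=N / 2)


class TestConfigValidation:
    def test_bad_reduction(self):
        with pytest.raises(ValueError):
            nl.IRGNMConfig(reduction_q=1.5)

    def test_bad_strength(self):
        with pytest.raises(ValueError):
            nl.RegSpec("L2", -1.0)

    def test_unknown_reg_type(self):
        with pytest.raises(ValueError):
            nl.RegSpec("TV", 0.1)


class TestIrgnm:
    def _single_voxel_problem(self):
        N, T = 4, 12
        times = TimeGrid(np.linspace(0.02, 3.0, T))
        traj = dense_frame_traj(N, T)
        model = IRFlashModel(times)
        sens = np.ones((1, N, N), complex)
        op = ParamOperator(model, traj, N, sens=sens)
        true = {"Mss": np.full((N, N), 0.4 + 0j),
                "M0": np.full((N, N), 0.9 + 0j),
                "R1s": np.full((N, N), 2.7)}
        return op, model, times, true

    def test_converges_to_grid_search_oracle(self):
        op, model, times, true = self._single_voxel_problem()
        y = op.forward(true)
        x0 = {"Mss": np.full((4, 4), 1 + 0j), "M0": np.full((4, 4), 1 + 0j),
              "R1s": np.full((4, 4), 1.5)}
        cfg = nl.IRGNMConfig(newton_steps=12, reduction_q=0.3,
                             inner_iters=100, inner_solver="CG")
        x, info = nl.irgnm(op, y, x0, cfg, [nl.RegSpec("L2", 1.0)])

        # independent oracle: coarse-to-fine R1* grid search with the
        # closed-form linear subproblem for (Mss, M0)
        sig = model.signal(true)[:, 0, 0]
        t = times.values

        def grid_best(grid):
            best = (np.inf, None, None)
            for r1 in grid:
                E = np.exp(-t * r1)
                A = np.stack([1 - E, -E], axis=1)
                p, *_ = np.linalg.lstsq(A, sig, rcond=None)
                sse = np.linalg.norm(A @ p - sig) ** 2
                if sse < best[0]:
                    best = (sse, p, r1)
            return best

        _, p, r1 = grid_best(np.linspace(0.5, 5, 2000))
        _, p, r1 = grid_best(np.linspace(r1 - 0.01, r1 + 0.01, 2000))
        assert abs(x["R1s"][0, 0] - r1) / r1 < 1e-3
        assert abs(x["Mss"][0, 0] - p[0]) / abs(p[0]) < 1e-3
        assert abs(x["M0"][0, 0] - p[1]) / abs(p[1]) < 1e-3

    def test_linear_problem_one_step_matches_normal_equations(self, rng):
        # static single-frame model: forward is linear in M0p at R2 = 0
        N, T = 8, 1
        times = TimeGrid(np.array([0.0]))
        traj = dense_frame_traj(N, T)
        model = SpinEchoModel(times)
        op = ParamOperator(model, traj, N, sens=np.ones((1, N, N), complex))
        true_img = rng.standard_normal((N, N)) + 1j * rng.standard_normal((N, N))
        y = op.forward({"M0p": true_img, "R2": np.zeros((N, N))})
        x0 = {"M0p": np.zeros((N, N), complex), "R2": np.zeros((N, N))}
        lam = 0.3
        cfg = nl.IRGNMConfig(newton_steps=1, lambda0=lam, inner_iters=400,
                             inner_solver="CG", cg_tol=1e-12,
                             scaling={"M0p": 1.0, "R2": 1.0}, backtrack=0)
        x, _ = nl.irgnm(op, y, x0, cfg, [nl.RegSpec("L2", 1.0)])
        # optimality of the regularized linear solution:
        # J^H (J x - y) + lam (x - x0) = 0
        lin = op.linearize(x0)
        resid = lin.apply({"M0p": x["M0p"], "R2": x["R2"]}) - y
        grad = lin.adjoint(resid)["M0p"] + lam * (x["M0p"] - x0["M0p"])
        assert np.abs(grad).max() < 1e-6 * np.abs(x["M0p"]).max()

    def test_divergence_flag_returns_best_iterate(self):
        op, model, times, true = self._single_voxel_problem()
        y = op.forward(true)

        class SignFlipped:
            """Adversarial operator: Jacobian with the wrong sign."""

            model = op.model

            def forward(self, x):
                return op.forward(x)

            def linearize(self, x):
                lin = op.linearize(x)

                class L:
                    def apply(self, dx):
                        return -lin.apply(dx)

                    def adjoint(self, dy):
                        return lin.adjoint(dy)
                return L()

        x0 = {"Mss": np.full((4, 4), 1 + 0j), "M0": np.full((4, 4), 1 + 0j),
              "R1s": np.full((4, 4), 1.5)}
        cfg = nl.IRGNMConfig(newton_steps=8, inner_iters=10,
                             inner_solver="CG", backtrack=0,
                             scaling={"Mss": 1.0, "M0": 1.0, "R1s": 1.0})
        x, info = nl.irgnm(SignFlipped(), y, x0, cfg, [nl.RegSpec("L2", 1.0)])
        assert info["diverged"]
        # best iterate: residual of the result equals the smallest logged
        res = float(np.linalg.norm(y - op.forward(x)))
        assert res <= min(info["residuals"][:-1]) * (1 + 1e-9)


class TestScalingInvariance:
    def test_linear_maps_scale_rates_do_not(self):
        from mbqmri.experiments import sim_t2_dataset
        data, sens, _ = sim_t2_dataset(grid_size=32, n_excitations=9,
                                       n_echoes=8, noise_rel=0.0, seed=3)
        cfg = nl.IRGNMConfig(newton_steps=4, inner_iters=20,
                             inner_solver="CG")
        x1, t2_1, _ = nl.recon_relaxometry(data, "T2", sens, cfg=cfg,
                                           regs=[nl.RegSpec("L2", 1.0)])
        c = 3.7
        data2 = KSpaceData(c * data.y, data.traj, data.times, "SE")
        x2, t2_2, _ = nl.recon_relaxometry(data2, "T2", sens, cfg=cfg,
                                           regs=[nl.RegSpec("L2", 1.0)])
        scale = np.abs(c * x1["M0p"]).max()
        np.testing.assert_allclose(x2["M0p"], c * x1["M0p"], rtol=1e-3,
                                   atol=1e-5 * scale)
        np.testing.assert_allclose(x2["R2"], x1["R2"], rtol=1e-3, atol=1e-3)


class TestWaterfatInit:
    def test_three_point_separation_exact_on_model(self):
        from mbqmri.signal_models import default_fat_spectrum
        spec = default_fat_spectrum(3.0)
        te = np.array([1.4e-3, 2.8e-3, 4.2e-3])
        W = np.array([[1.0 + 0.2j]])
        F = np.array([[0.4 - 0.1j]])
        cs = spec.phasor(te)
        imgs = (W[None] + F[None] * cs[:, None, None])
        out = nl.waterfat_3pt_init(imgs, te, spec)
        np.testing.assert_allclose(out["W"], W, atol=1e-10)
        np.testing.assert_allclose(out["F"], F, atol=1e-10)

    def test_requires_three_echoes(self):
        from mbqmri.signal_models import default_fat_spectrum
        with pytest.raises(ValueError):
            nl.waterfat_3pt_init(np.zeros((2, 4, 4), complex),
                                 np.array([1e-3, 2e-3]),
                                 default_fat_spectrum(3.0))


class TestWaterfatRecon:
    def test_single_voxel_fat_fraction(self):
        """Mixed voxel W=1, F=0.5: recovered fat fraction 1/3 within 1%."""
        from mbqmri.encoding import ParamOperator
        from mbqmri.signal_models import MEGREModel, default_fat_spectrum
        N = 4
        spectrum = default_fat_spectrum(3.0)
        echoes = TimeGrid(1.37e-3 + 1.34e-3 * np.arange(7))
        traj = dense_frame_traj(N, 7)
        model = MEGREModel(echoes, spectrum)
        op = ParamOperator(model, traj, N, sens=np.ones((1, N, N), complex))
        true = {"W": np.full((N, N), 1.0 + 0j),
                "F": np.full((N, N), 0.5 + 0j),
                "R2s": np.full((N, N), 40.0),
                "fB0": np.full((N, N), 15.0)}
        y = op.forward(true)
        x0 = {"W": np.full((N, N), 0.8 + 0j),
              "F": np.full((N, N), 0.2 + 0j),
              "R2s": np.zeros((N, N)), "fB0": np.zeros((N, N))}
        cfg = nl.IRGNMConfig(newton_steps=10, reduction_q=0.3,
                             inner_iters=100, inner_solver="CG")
        x, _ = nl.irgnm(op, y, x0, cfg, [nl.RegSpec("L2", 1.0)])
        ff = abs(x["F"][0, 0]) / (abs(x["W"][0, 0]) + abs(x["F"][0, 0]))
        assert abs(ff - 1.0 / 3.0) < 0.01
        assert abs(np.real(x["fB0"][0, 0]) - 15.0) < 1.0

    def test_water_only_phantom_low_fat_leakage(self):
        """All-water phantom: recovered |F| stays <= 1% of |W| (ROI mean)."""
        from mbqmri.data import KSpaceData
        from mbqmri.metrics import ROI
        from mbqmri.phantom import (Ellipse, PhantomSpec,
                                    circular_coil_model, simulate_kspace)
        from mbqmri.signal_models import default_fat_spectrum
        from mbqmri.trajectories import multi_echo_trajectory, \
            tiny_golden_angle
        N = 64
        spec = PhantomSpec(
            "MEGRE",
            (Ellipse((0.0, 0.0), (0.40, 0.36)),
             {"W": 1.0, "F": 0.0, "R2s": 30.0, "fB0": 0.0}),
            [(Ellipse((-0.15, 0.0), (0.10, 0.10)),
              {"W": 0.6, "F": 0.0, "R2s": 60.0, "fB0": 0.0})],
            extras={"field_strength": 3.0})
        coils = circular_coil_model(8)
        traj = multi_echo_trajectory(33, 7, N + 1, tiny_golden_angle(1),
                                     N / 2, angle_mode="per_excitation")
        times = 1.37e-3 + 1.34e-3 * np.arange(7)
        spectrum = default_fat_spectrum(3.0)
        y = simulate_kspace(spec, coils, traj, times, 0.0, 1,
                            spectrum=spectrum)
        data = KSpaceData(y, traj, times, "MEGRE",
                          meta={"field_strength": 3.0})
        x, _ = nl.recon_waterfat(data, coils.grid_maps(N))
        roi = ROI("bg", (0.1, -0.12), 0.08).mask(N)
        assert np.abs(x["F"][roi]).mean() <= 0.01 * np.abs(x["W"][roi]).mean()
        assert np.abs(np.real(x["fB0"][roi]).mean()) <= 1.0


class TestNoiseScaling:
    def test_roi_sd_decreases_with_snr(self):
        """Map noise shrinks when the data SNR improves (T2 pipeline)."""
        from mbqmri.experiments import sim_t2_dataset
        from mbqmri.metrics import ROI
        sds = []
        for frac in (0.02, 0.002):
            data, sens, _ = sim_t2_dataset(grid_size=32, n_excitations=13,
                                           n_echoes=8, noise_rel=frac,
                                           seed=11)
            cfg = nl.IRGNMConfig(newton_steps=6, inner_iters=25,
                                 inner_solver="CG", lambda_min=0.01)
            x, t2map, _ = nl.recon_relaxometry(
                data, "T2", sens, cfg=cfg, regs=[nl.RegSpec("L2", 0.1)])
            bg = ROI("bg", (0.0, 0.0), 0.10).mask(32)
            sds.append(np.nanstd(np.real(x["R2"])[bg]))
        assert sds[1] < sds[0]


class TestFlowErrors:
    def test_wrong_encoding_count(self):
        from mbqmri.experiments import sim_t2_dataset
        data, sens, _ = sim_t2_dataset(grid_size=32, n_excitations=5,
                                       n_echoes=4, noise_rel=0.0, seed=1)
        with pytest.raises(ValueError):
            nl.recon_flow(data, sens, venc=150.0)

    def test_model_mismatch(self):
        from mbqmri.experiments import sim_t2_dataset
        data, sens, _ = sim_t2_dataset(grid_size=32, n_excitations=5,
                                       n_echoes=4, noise_rel=0.0, seed=1)
        with pytest.raises(ValueError):
            nl.recon_relaxometry(data, "T1", sens)
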
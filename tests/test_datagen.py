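import numpy as np
import pytest
from scipy.integrate import solve_ivp

from fracpde import datagen as dg
from fracpde.grids import FieldSnapshot, SpatialGrid, TrajectoryDataset


class TestInitialConditions:
    def test_single_cosine_mode_survives_normalization(self):
        grid = dg.example1_grid(32)
        n = 2 * 3 + 1
        a = np.zeros((n, n))
        a[3 + 1, 3 + 0] = 1.0  # the cos(2x) mode
        z = np.zeros((n, n))
        w0 = dg.eq18_field(grid, a, z, z, z)
        x, _ = grid.meshgrid()
        assert np.allclose(w0, np.cos(2 * x))

    def test_same_seed_is_bit_identical(self):
        grid = dg.example1_grid(16)
        spec = dg.InitialConditionSpec()
        u1, v1 = dg.random_initial_condition(grid, spec, seed=42)
        u2, v2 = dg.random_initial_condition(grid, spec, seed=42)
        assert np.array_equal(u1.values, u2.values)
        assert np.array_equal(v1.values, v2.values)

    def test_max_normalization_bound(self):
        # the normalized field w0 / max|w0| has sup-norm exactly 1, so the
        # offset initial state satisfies |u0 - c1| <= 1 with equality
        # attained at some grid point
        grid = dg.example1_grid(48)
        rng = np.random.default_rng(7)
        n = 2 * 3 + 1
        coef = [rng.standard_normal((n, n)) for _ in range(4)]
        w0 = dg.eq18_field(grid, *coef)
        w = w0 / np.max(np.abs(w0))
        assert np.max(np.abs(w)) == 1.0
        c1 = 0.3
        u0 = w + c1
        assert np.max(np.abs(u0 - c1)) <= 1.0
        # the offset bounds also hold for the library-drawn states
        u0s, v0s = dg.random_initial_condition(
            grid, dg.InitialConditionSpec(), seed=7
        )
        assert u0s.values.max() - u0s.values.min() <= 2.0 + 1e-12
        assert v0s.values.max() - v0s.values.min() <= 2.0 + 1e-12


class TestSimulator2D:
    def test_one_step_from_rest_matches_source_terms(self):
        grid = dg.example1_grid(16)
        sys1 = dg.example1_system()
        z = FieldSnapshot(np.zeros(grid.shape), 0.0, grid)
        dt = 1.0 / 1600.0
        u, v = dg.simulate_true_2d(sys1, z, z, dt, dt)
        # rational terms vanish at u = 0, so du = dt*1, dv = dt*0.4 + O(dt^2)
        assert np.allclose(u[1], dt * 1.0, rtol=2e-3)
        assert np.allclose(v[1], dt * 0.4, rtol=2e-3)

    def test_uniform_field_reduces_to_ode(self):
        grid = dg.example1_grid(12)
        sys1 = dg.example1_system()
        u0 = FieldSnapshot(np.full(grid.shape, 0.7), 0.0, grid)
        v0 = FieldSnapshot(np.full(grid.shape, 1.1), 0.0, grid)
        u, v = dg.simulate_true_2d(sys1, u0, v0, 1 / 1600, 0.15)

        def ode(t, y):
            r1, r2 = sys1.reaction(y[0], y[1], None)
            return [r1, r2]

        sol = solve_ivp(ode, [0, 0.15], [0.7, 1.1], rtol=1e-11, atol=1e-13)
        assert abs(u[-1].mean() - sol.y[0, -1]) < 1e-7
        assert abs(v[-1].mean() - sol.y[1, -1]) < 1e-7

    def test_rk2_convergence_order(self):
        # halving the step reduces the uniform-field error by about 4x
        grid = dg.example1_grid(8)
        sys1 = dg.example1_system()
        u0 = FieldSnapshot(np.full(grid.shape, 0.4), 0.0, grid)
        v0 = FieldSnapshot(np.full(grid.shape, 0.9), 0.0, grid)

        def ode(t, y):
            r1, r2 = sys1.reaction(y[0], y[1], None)
            return [r1, r2]

        ref = solve_ivp(ode, [0, 0.1], [0.4, 0.9], rtol=1e-12, atol=1e-14)
        errs = []
        for dt in (1e-3, 5e-4):
            u, v = dg.simulate_true_2d(sys1, u0, v0, dt, 0.1)
            errs.append(abs(u[-1].mean() - ref.y[0, -1]))
        ratio = errs[0] / errs[1]
        assert 3.0 < ratio < 5.0

    def test_zero_system_is_constant(self):
        grid = dg.example1_grid(8)
        zero = dg.TrueSystemSpec(
            0.0, 0.0,
            lambda u, v, I: 0.0 * u, lambda u, v, I: 0.0 * v,
            lambda u, v: 0.0 * u, lambda u, v: 0.0 * v, dim=2,
        )
        rng = np.random.default_rng(0)
        u0 = FieldSnapshot(rng.random(grid.shape), 0.0, grid)
        v0 = FieldSnapshot(rng.random(grid.shape), 0.0, grid)
        u, v = dg.simulate_true_2d(zero, u0, v0, 0.01, 0.05)
        assert np.array_equal(u[0], u[-1])

    def test_pure_diffusion_conserves_mass(self):
        # zero-flux mirror boundary: the discrete Laplacian moves no mass
        # through the boundary, so plain diffusion conserves the total
        grid = dg.example1_grid(16)
        diff_only = dg.TrueSystemSpec(
            0.3, 0.4,
            lambda u, v, I: 0.0 * u, lambda u, v, I: 0.0 * v,
            lambda u, v: 0.0 * u, lambda u, v: 0.0 * v, dim=2,
        )
        rng = np.random.default_rng(3)
        u0 = FieldSnapshot(rng.random(grid.shape), 0.0, grid)
        v0 = FieldSnapshot(rng.random(grid.shape), 0.0, grid)
        u, v = dg.simulate_true_2d(diff_only, u0, v0, 1e-3, 0.02)
        assert np.isclose(u[-1].sum(), u[0].sum(), rtol=1e-12)
        lap = dg.laplacian(u0.values, grid)
        assert abs(lap.sum()) < 1e-9 * np.abs(lap).max()

    def test_blow_up_raises_diagnostic(self):
        grid = dg.example1_grid(8)
        unstable = dg.TrueSystemSpec(
            0.0, 0.0,
            lambda u, v, I: u * u * 1e6, lambda u, v, I: 0.0 * v,
            lambda u, v: 0.0 * u, lambda u, v: 0.0 * v, dim=2,
        )
        u0 = FieldSnapshot(np.full(grid.shape, 10.0), 0.0, grid)
        with pytest.raises(dg.BlowUpError, match="step"):
            dg.simulate_true_2d(unstable, u0, u0, 0.1, 1.0)


class TestSimulator1D:
    def test_linear_decay_closed_form(self):
        # with u = 0 the second equation is v_t = 10 v_xx - 0.4 v; a uniform
        # state decays as exp(-0.4 t) up to the first-order Euler error
        sys2 = dg.example2_system()
        grid = dg.example2_grid(120)
        u0 = FieldSnapshot(np.zeros(120), 0.0, grid)
        v0 = FieldSnapshot(np.ones(120), 0.0, grid)
        u, v = dg.simulate_true_1d(sys2, u0, v0, 0.01, 0.75)
        exact = np.exp(-0.4 * 0.75)
        assert abs(v[-1].mean() - exact) < 0.4 * 0.01  # O(dt)
        assert np.allclose(u[-1], 0.0)

    def test_restriction_of_constant(self):
        sys2 = dg.example2_system()
        grid = dg.example2_grid(120)
        u0 = FieldSnapshot(np.full(120, 0.0259), 0.0, grid)
        v0 = FieldSnapshot(np.full(120, 0.06475), 0.0, grid)
        u, v = dg.simulate_true_1d(sys2, u0, v0, 0.01, 0.02, restrict_to=40)
        assert u.shape[1] == 40
        assert np.allclose(u[0], u[0][0])  # restriction of uniform stays uniform

    def test_integral_of_uniform_state(self):
        grid = dg.example2_grid(200)
        c = 0.0259
        val = np.sum(grid.quad_weights * np.full(200, c))
        assert np.isclose(val, 5 * np.pi * c, rtol=1e-12)


class TestObservationModel:
    def test_zero_noise_is_identity(self, tiny_ex2_data):
        tr = tiny_ex2_data["truth"]
        out = dg.add_noise(tr, 0.0, take_abs=False, seed=3)
        assert out is tr

    def test_noise_magnitude_matches_prescription(self):
        grid = dg.example1_grid(64)
        rng = np.random.default_rng(0)
        u = rng.normal(1.0, 0.5, size=(1, 20) + grid.shape)
        traj = TrajectoryDataset(u, u.copy(), grid, 0.01)
        noisy = dg.add_noise(traj, 0.05, seed=9)
        resid = noisy.u - traj.u
        sigma = np.std(traj.u[0])
        assert np.isclose(np.std(resid), 0.05 * sigma, rtol=0.02)

    def test_take_abs_gives_nonnegative_fields(self):
        grid = dg.example2_grid(50)
        u = np.full((1, 3, 50), -0.5)
        traj = TrajectoryDataset(u, u.copy(), grid, 0.05)
        noisy = dg.add_noise(traj, 0.01, take_abs=True, seed=1)
        assert (noisy.u >= 0).all() and (noisy.v >= 0).all()

    def test_seeded_noise_is_reproducible(self, tiny_ex2_data):
        tr = tiny_ex2_data["truth"]
        a = dg.add_noise(tr, 0.01, seed=5)
        b = dg.add_noise(tr, 0.01, seed=5)
        assert np.array_equal(a.u, b.u)


class TestSubsampleSplit:
    def _fine(self, grid, n_init=3, n_steps=32):
        rng = np.random.default_rng(0)
        u = rng.random((n_init, n_steps + 1) + grid.shape)
        return u, rng.random((n_init, n_steps + 1) + grid.shape)

    def test_identity_subsampling(self):
        grid = dg.example2_grid(20)
        fu, fv = self._fine(grid, n_steps=5)
        tr, va, te = dg.subsample_and_split(fu, fv, grid, 0.01, 0.01, 5, (1, 1, 1))
        assert np.array_equal(tr.u[0], fu[0])

    def test_observation_stride(self):
        grid = dg.example2_grid(20)
        fu, fv = self._fine(grid, n_steps=32)
        tr, _, _ = dg.subsample_and_split(
            fu, fv, grid, 1 / 1600, 0.01, 2, (3, 0, 0)
        )
        assert np.array_equal(tr.u[:, 1], fu[:, 16])  # every 16th fine step

    def test_all_in_train(self):
        grid = dg.example2_grid(20)
        fu, fv = self._fine(grid, n_init=12, n_steps=4)
        tr, va, te = dg.subsample_and_split(fu, fv, grid, 0.05, 0.05, 4, (12, 0, 0))
        assert tr.n_init == 12 and va.n_init == 0 and te.n_init == 0

    def test_non_divisible_stride_rejected(self):
        grid = dg.example2_grid(20)
        fu, fv = self._fine(grid, n_steps=10)
        with pytest.raises(ValueError, match="integer multiple"):
            dg.subsample_and_split(fu, fv, grid, 0.003, 0.01, 3, (3, 0, 0))
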
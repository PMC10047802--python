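import numpy as np
import pytest

from fracpde import operators as op
from fracpde.grids import FieldSnapshot, SpatialGrid


class TestMomentTransform:
    def test_centered_delta_has_unit_zeroth_moment(self):
        q = np.zeros((3, 3))
        q[1, 1] = 1.0
        m = op.moments_from_filter(op.Filter(q)).values
        expect = np.zeros((3, 3))
        expect[0, 0] = 1.0
        assert np.allclose(m, expect)

    def test_central_difference_moments(self):
        # q[+1,0]=1/2, q[-1,0]=-1/2 approximates d/dx: m10=1, m00=m20=0
        q = np.zeros((3, 3))
        q[2, 1] = 0.5
        q[0, 1] = -0.5
        m = op.moments_from_filter(op.Filter(q)).values
        assert np.isclose(m[1, 0], 1.0)
        assert np.isclose(m[0, 0], 0.0)
        assert np.isclose(m[2, 0], 0.0)

    @pytest.mark.parametrize("shape", [(5,), (3, 3), (5, 5), (19,)])
    def test_round_trip_is_bijective(self, shape, rng):
        q = rng.standard_normal(shape)
        m = op.moments_from_filter(op.Filter(q))
        q2 = op.filter_from_moments(m).kernel
        assert np.allclose(q2, q, atol=1e-10)

    def test_first_moment_kernel_differentiates_a_ramp(self):
        m = np.zeros(3)
        m[1] = 1.0
        bank = op.FilterBank(1, 3, spacing=0.25, orders=[(1,)])
        x = np.arange(32) * 0.25
        out = op.apply_derivative(bank, (1,), x)
        assert np.allclose(out[1:-1], 1.0)


class TestConstrainedBank:
    def test_parameter_counts_match_benchmark_settings(self):
        assert op.example1_bank(10 / 64).n_trainable == 52
        assert op.example2_bank(5 * np.pi / 200).n_trainable == 32

    def test_fixed_entries_survive_training_updates(self, rng):
        bank = op.example1_bank(10 / 64)
        before = {o: bank.moments[o].values.copy() for o in bank.orders}
        bank.set_free_values(rng.standard_normal(bank.n_trainable))
        for o in bank.orders:
            mm = bank.moments[o]
            assert np.array_equal(
                mm.values[mm.fixed_mask], before[o][mm.fixed_mask]
            )

    def test_derivative_exact_on_linear_field(self):
        grid = SpatialGrid(2, (-5.0, 5.0), 32)
        bank = op.FilterBank(2, 3, grid.spacing, [(1, 0)])
        x, _ = grid.meshgrid()
        out = op.apply_derivative(bank, (1, 0), FieldSnapshot(x, 0.0, grid))
        assert np.allclose(out[1:-1, 1:-1], 1.0, atol=1e-10)

    def test_second_derivative_kills_constants(self):
        bank = op.example1_bank(10 / 64)
        const = np.full((64, 64), 3.7)
        out = op.apply_derivative(bank, (2, 0), const)
        assert np.allclose(out, 0.0, atol=1e-8)

    @pytest.mark.parametrize("example,sizes", [
        (1, (32, 64, 128)),
        (2, (64, 128, 256)),
    ])
    def test_empirical_convergence_order_at_least_two(self, example, sizes):
        """Every constrained kernel keeps >= 2nd-order accuracy on smooth
        fields, including with randomly perturbed free moments."""
        perturb = np.random.default_rng(0)
        errs = {}
        for n in sizes:
            dim = 2 if example == 1 else 1
            grid = SpatialGrid(dim, (-np.pi, np.pi), n)
            bank = (
                op.example1_bank(grid.spacing)
                if example == 1
                else op.example2_bank(grid.spacing)
            )
            bank.set_free_values(
                0.05 * np.random.default_rng(0).standard_normal(bank.n_trainable)
            )
            if example == 1:
                x, y = grid.meshgrid()
                f = np.sin(x) * np.cos(y)
                targets = {(2, 0): -f, (0, 2): -f}
            else:
                (x,) = grid.meshgrid()
                f = np.sin(x)
                targets = {(1,): np.cos(x), (2,): -f}
            for o, target in targets.items():
                out = op.apply_derivative(bank, o, f)
                interior = (slice(10, -10),) * dim
                errs.setdefault(o, []).append(
                    np.max(np.abs(out[interior] - target[interior]))
                )
        for o, es in errs.items():
            if max(es) < 1e-10:
                continue  # fully constrained stencil: exact to roundoff
            for e1, e2 in zip(es, es[1:]):
                assert e1 / e2 > 3.4, f"order {o}: ratio {e1 / e2}"


class TestIntegralOperator:
    def test_uniform_state(self):
        grid = SpatialGrid(1, (-2.5 * np.pi, 2.5 * np.pi), 200)
        f = FieldSnapshot(np.full(200, 2.0), 0.0, grid)
        out = op.integral_operator(f)
        assert np.allclose(out, 10 * np.pi)
        assert out.shape == (200,)

    def test_odd_function_integrates_to_zero(self):
        grid = SpatialGrid(1, (-np.pi, np.pi), 400)
        (x,) = grid.meshgrid()
        out = op.integral_operator(FieldSnapshot(np.sin(x), 0.0, grid))
        assert abs(out[0]) < 1e-10

    def test_quadratic_closed_form(self):
        grid = SpatialGrid(1, (-1.0, 1.0), 201)
        (x,) = grid.meshgrid()
        out = op.integral_operator(FieldSnapshot(x**2, 0.0, grid))
        assert abs(out[0] - 2.0 / 3.0) < 1e-4

    def test_rejected_on_2d_grid(self):
        grid = SpatialGrid(2, (-1.0, 1.0), 8)
        f = FieldSnapshot(np.zeros((8, 8)), 0.0, grid)
        with pytest.raises(ValueError, match="1-D"):
            op.integral_operator(f)


class TestSerialization:
    def test_bank_round_trips_through_dict(self, rng):
        bank = op.example2_bank(5 * np.pi / 200)
        bank.set_free_values(rng.standard_normal(bank.n_trainable))
        clone = op.FilterBank.from_dict(bank.to_dict())
        for o in bank.orders:
            assert np.allclose(clone.kernel(o), bank.kernel(o))
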
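import numpy as np
import pytest

from fracpde import autodiff as ad
from fracpde import datagen as dg
from fracpde.grids import TrajectoryDataset
from fracpde.training import (
    LossConfig,
    PDEModel,
    generic_rollout_loss,
    huber,
    loss_total,
    rollout,
    train,
)

from conftest import make_constant_dataset


class TestHuber:
    @pytest.mark.parametrize("x,s,expect", [
        (2.0, 1.0, 1.5),       # linear branch |x| - s/2
        (0.5, 1.0, 0.125),     # quadratic branch x^2 / (2s)
        (-2.0, 1.0, 1.5),
    ])
    def test_closed_form(self, x, s, expect):
        assert np.isclose(huber(x, s), expect)

    def test_continuous_at_threshold(self):
        s = 0.37
        below = huber(s * (1 - 1e-9), s)
        above = huber(s * (1 + 1e-9), s)
        assert np.isclose(below, s / 2, atol=1e-8)
        assert np.isclose(above, s / 2, atol=1e-8)

    def test_tensor_and_numpy_agree(self, rng):
        x = rng.normal(0, 0.05, size=40)
        t = huber(ad.leaf(x), 0.01)
        assert np.allclose(t.value, huber(x, 0.01))


class TestRollout:
    def test_zero_rhs_is_constant(self, rng):
        u0 = ad.constant(rng.random((2, 8)))
        v0 = ad.constant(rng.random((2, 8)))
        states, ok = rollout(
            lambda u, v: (0.0 * u, 0.0 * v), u0, v0, 4, 0.1
        )
        assert ok
        assert np.allclose(states[-1][0].value, u0.value)

    def test_constant_rhs_closed_form(self):
        u0 = ad.constant(np.zeros(5))
        states, ok = rollout(
            lambda u, v: (ad.constant(np.full(5, 2.0)), 0.0 * v),
            u0, u0, 3, 0.1,
        )
        assert np.allclose(states[-1][0].value, 3 * 0.1 * 2.0)

    def test_true_rhs_one_block_matches_fine_simulation(self):
        # preloaded true dynamics + exact stencils: a single Delta-t block
        # agrees with the RK2 reference to O(dt^2) + O(dx^2)
        data = dg.make_example_dataset(1, 0.0, seed=2, n_init=2, n_space=32,
                                       sizes=(2, 0, 0))
        grid = data["grid"]
        sys1 = data["system"]

        def rhs(u, v):
            uu, vv = u.value, v.value
            r1, r2 = sys1.reaction(uu, vv, None)
            return (
                ad.constant(sys1.d1 * dg.laplacian(uu, grid) + r1),
                ad.constant(sys1.d2 * dg.laplacian(vv, grid) + r2),
            )

        tr = data["truth"]
        states, ok = rollout(
            rhs, ad.constant(tr.u[:, 0]), ad.constant(tr.v[:, 0]), 1, 0.01
        )
        assert ok
        err = np.max(np.abs(states[0][0].value - tr.u[:, 1]))
        assert err < 2e-2  # dt^2 and coarse-grid dx^2 scale errors

    def test_non_finite_state_truncates(self):
        u0 = ad.constant(np.full(4, 10.0))

        def explode(u, v):
            return (u * u * u * 1e8, 0.0 * v)

        states, ok = rollout(explode, ad.constant(np.full(4, 1e5)),
                             u0, 5, 1.0)
        assert not ok
        assert len(states) < 5


class TestLoss:
    def test_perfect_model_has_zero_data_loss(self, grid1d_small):
        ds = make_constant_dataset(grid1d_small, [1.0, 1.0, 1.0], [2.0, 2.0, 2.0])
        model = PDEModel(2, grid1d_small, seed=None)  # all-zero networks
        cfg = LossConfig(0.0, 0.0, 0.01, 2, 0.05)
        f, g, parts = loss_total(model, ds, cfg)
        assert parts["data"] == 0.0
        assert f == 0.0

    def test_total_reduces_to_data_without_regularization(self, tiny_ex2_noisy):
        model = PDEModel(2, tiny_ex2_noisy["grid"], seed=4)
        cfg = LossConfig(0.0, 0.0, 0.01, 3, 0.05, teacher_forcing=True)
        f, _, parts = loss_total(model, tiny_ex2_noisy["train"], cfg)
        assert np.isclose(f, parts["data"])

    def test_constant_offset_hand_value(self, grid1d_small):
        # one block, one trajectory, v-offset delta: L = ||delta||_2^2 / dt^2
        delta, dt = 0.3, 0.05
        ds = make_constant_dataset(grid1d_small, [1.0, 1.0], [2.0, 2.0 + delta],
                                   dt=dt)
        model = PDEModel(2, grid1d_small, seed=None)
        cfg = LossConfig(0.0, 0.0, 0.01, 1, dt)
        _, _, parts = loss_total(model, ds, cfg)
        expect = grid1d_small.cell_measure * grid1d_small.n_points * delta**2 / dt**2
        assert np.isclose(parts["data"], expect)

    def test_gradient_matches_finite_differences(self, tiny_ex2_noisy, rng):
        model = PDEModel(2, tiny_ex2_noisy["grid"], seed=7)
        cfg = LossConfig(1e-7, 1e-6, 0.01, 3, 0.05, teacher_forcing=True)
        vec = model.pack()
        f, g, _ = loss_total(model, tiny_ex2_noisy["train"], cfg, vec)
        eps = 1e-6
        for i in rng.choice(len(vec), size=10, replace=False):
            vp, vm = vec.copy(), vec.copy()
            vp[i] += eps
            vm[i] -= eps
            fp, _, _ = loss_total(model, tiny_ex2_noisy["train"], cfg, vp,
                                  want_grad=False)
            fm, _, _ = loss_total(model, tiny_ex2_noisy["train"], cfg, vm,
                                  want_grad=False)
            fd = (fp - fm) / (2 * eps)
            assert abs(fd - g[i]) <= 1e-4 * max(1.0, abs(fd), abs(g[i]))

    def test_teacher_forced_and_free_agree_on_one_block(self, tiny_ex2_noisy):
        model = PDEModel(2, tiny_ex2_noisy["grid"], seed=3)
        vec = model.pack()
        _, _, _, rhs, _ = model.rhs_closure(vec)
        l1, _ = generic_rollout_loss(rhs, tiny_ex2_noisy["train"], 1, 0.05, False)
        _, _, _, rhs2, _ = model.rhs_closure(vec)
        l2, _ = generic_rollout_loss(rhs2, tiny_ex2_noisy["train"], 1, 0.05, True)
        assert np.isclose(float(l1.value), float(l2.value))


class TestTrain:
    def _small_setup(self, tiny_ex2_noisy):
        model = PDEModel(2, tiny_ex2_noisy["grid"], seed=5)
        cfg = LossConfig(1.88e-7, 1.62e-6, 0.01, 4, 0.05, teacher_forcing=True)
        return model, cfg

    def test_training_reduces_the_loss(self, tiny_ex2_noisy):
        model, cfg = self._small_setup(tiny_ex2_noisy)
        data = tiny_ex2_noisy["train"].truncate_blocks(4)
        f0, _, _ = loss_total(model, data, cfg, want_grad=False)
        tm = train(model, data, cfg, n_stages=2, total_blocks=4, max_iter=40,
                   stage_rounds=1)
        f1, _, _ = loss_total(model, data, cfg, want_grad=False)
        assert f1 < f0
        assert [h["blocks"] for h in tm.history[:2]] == [2, 4]

    def test_fixed_seed_reproduces_history(self, tiny_ex2_noisy):
        histories = []
        for _ in range(2):
            model, cfg = self._small_setup(tiny_ex2_noisy)
            data = tiny_ex2_noisy["train"].truncate_blocks(4)
            tm = train(model, data, cfg, n_stages=2, total_blocks=4,
                       max_iter=25, stage_rounds=1)
            histories.append([h["loss"] for h in tm.history])
        assert histories[0] == histories[1]

    def test_stage_structure_of_curriculum(self, tiny_ex2_noisy):
        model, cfg = self._small_setup(tiny_ex2_noisy)
        tm = train(model, tiny_ex2_noisy["train"], cfg, n_stages=5,
                   total_blocks=15, max_iter=2, stage_rounds=1,
                   lam_schedule="continuation")
        blocks = [h["blocks"] for h in tm.history]
        assert blocks == [3, 6, 9, 12, 15, 15]  # curriculum + polish
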
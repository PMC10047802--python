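import numpy as np
import pytest
import sympy as sp

from fracpde import compare as cmp
from fracpde import sparsify as spf
from fracpde.grids import TrajectoryDataset

u, v = sp.symbols("u v")


class TestKSTest:
    def test_identical_samples(self, rng):
        a = rng.standard_normal((50, 2))
        d, p = cmp.ks_two_sample(a, a.copy(), n_permutations=99, seed=0)
        assert d == 0.0
        assert p == 1.0

    def test_separated_distributions_are_detected(self, rng):
        a = rng.normal(0.0, 1.0, size=(200, 2))
        b = rng.normal(3.0, 1.0, size=(200, 2))
        _, p = cmp.ks_two_sample(a, b, n_permutations=199, seed=1)
        assert p < 0.01

    def test_statistic_is_symmetric(self, rng):
        a = rng.normal(0.0, 1.0, size=(60, 2))
        b = rng.normal(0.5, 1.2, size=(60, 2))
        d1, _ = cmp.ks_two_sample(a, b, n_permutations=0, seed=0)
        d2, _ = cmp.ks_two_sample(b, a, n_permutations=0, seed=0)
        assert np.isclose(d1, d2)

    def test_same_distribution_is_not_rejected_too_often(self, rng):
        rejections = 0
        for k in range(20):
            a = rng.standard_normal((80, 2))
            b = rng.standard_normal((80, 2))
            _, p = cmp.ks_two_sample(a, b, n_permutations=99, seed=k)
            rejections += p < 0.05
        assert rejections <= 4  # ~5% nominal, generous Monte-Carlo margin


class TestAdjustment:
    def test_singleton_is_unchanged(self):
        for method in ("bonferroni", "holm", "bh"):
            p_adj, _ = cmp.adjust_pvalues(np.array([0.01]), method)
            assert np.isclose(p_adj[0], 0.01)

    def test_bonferroni_scales_by_count(self):
        p = np.full(50, 0.01)
        p[0] = 0.01
        p_adj, rej = cmp.adjust_pvalues(p, "bonferroni")
        assert np.isclose(p_adj[0], 0.5)
        assert not rej[0]

    def test_rejection_ordering_invariant(self, rng):
        # Bonferroni is never more liberal than Holm, Holm never more
        # liberal than Benjamini-Hochberg
        for _ in range(50):
            p = rng.random(30) ** rng.integers(1, 4)
            counts = {}
            for m in ("bonferroni", "holm", "bh"):
                _, rej = cmp.adjust_pvalues(p, m)
                counts[m] = rej.sum()
            assert counts["bonferroni"] <= counts["holm"] <= counts["bh"]

    def test_familywise_error_control_under_the_null(self, rng):
        any_reject = {"bonferroni": 0, "holm": 0}
        reps = 250
        for _ in range(reps):
            p = rng.random(20)
            for m in any_reject:
                _, rej = cmp.adjust_pvalues(p, m)
                any_reject[m] += rej.any()
        for m, count in any_reject.items():
            assert count / reps <= 0.05 + 0.03  # nominal + Monte-Carlo margin

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            cmp.adjust_pvalues(np.array([0.5, 1.2]), "holm")


class TestDropSmallestTerm:
    def _dataset(self, grid1d_small, rng):
        uu = 0.5 + rng.random((1, 3, grid1d_small.n_points))
        return TrajectoryDataset(uu, uu.copy(), grid1d_small, 0.05)

    def test_smallest_norm_interaction_removed(self, grid1d_small, rng):
        ds = self._dataset(grid1d_small, rng)
        model = spf.SparseModel([
            spf.SparseTerm("u", "mono", u, coeff=5.0),
            spf.SparseTerm("v", "mono", v, coeff=0.01),
        ], field="u")
        out = cmp.drop_smallest_term(model, ds)
        assert out.term_labels() == ["u"]
        assert out.stage == "PHrsmPDE"

    def test_diffusion_is_never_removed(self, grid1d_small, rng):
        ds = self._dataset(grid1d_small, rng)
        model = spf.SparseModel([
            spf.SparseTerm("uxx", "diffusion", sp.Symbol("u_xx"), coeff=1e-9),
            spf.SparseTerm("u", "mono", u, coeff=5.0),
            spf.SparseTerm("v", "mono", v, coeff=1.0),
        ], field="u")
        out = cmp.drop_smallest_term(model, ds)
        assert "uxx" in out.term_labels()
        assert "v" not in out.term_labels()


class TestPosthocReport:
    def test_identical_models_are_never_rejected(self, rng):
        times = np.arange(1, 11) * 0.01
        samples = [rng.standard_normal((40, 2)) for _ in times]
        res = cmp.ResidualSeries([s.copy() for s in samples], times)
        res2 = cmp.ResidualSeries([s.copy() for s in samples], times)
        report = cmp.posthoc_compare(res1=res, res2=res2, n_permutations=49)
        assert all(n == 0 for n in report.rejections.values())

    def test_grossly_different_models_are_rejected_everywhere(self, rng):
        times = np.arange(1, 11) * 0.01
        res1 = cmp.ResidualSeries(
            [rng.normal(0, 0.01, (60, 2)) for _ in times], times
        )
        res2 = cmp.ResidualSeries(
            [rng.normal(1.0, 0.01, (60, 2)) for _ in times], times
        )
        report = cmp.posthoc_compare(res1, res2, n_permutations=199)
        assert report.rejections["bonferroni"] == len(times)

    def test_report_frame_layout(self, rng):
        times = np.array([0.01, 0.02])
        res = cmp.ResidualSeries([rng.random((20, 2)) for _ in times], times)
        report = cmp.posthoc_compare(res, res, n_permutations=19)
        frame = report.to_frame()
        assert {"time", "p_raw", "p_bonferroni", "p_holm", "p_bh"} <= set(
            frame.columns
        )
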
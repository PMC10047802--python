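import numpy as np
import pytest
import sympy as sp

from fracpde import datagen as dg
from fracpde import sparsify as spf
from fracpde.symnet import SymbolicModel, SymbolicTerm
from fracpde.training import LossConfig

u, v = sp.symbols("u v")


class TestMergeTerms:
    def test_near_degenerate_fraction_collapses_to_main_part(self):
        # u^2/(u+eps) = u - eps + eps^2/(u+eps); on u in [0.5, 2] everything
        # but the main part is negligible
        expr = SymbolicModel(
            [SymbolicTerm("rational", u**2, u + 0.001, 1)]
        )
        out = spf.merge_terms(expr, 1e-2, u_range=(0.5, 2.0), v_range=(0.0, 1.0))
        assert len(out.terms) == 1
        t = out.terms[0]
        assert t.den is None and t.num == u
        assert abs(float(t.coeff) - 1.0) < 1e-12

    def test_monomials_pass_through(self):
        expr = SymbolicModel([
            SymbolicTerm("mono", u * v, None, 2.0),
            SymbolicTerm("diffusion", sp.Symbol("u_xx"), None, 0.3),
        ])
        out = spf.merge_terms(expr, 1e-2)
        assert {sp.sstr(t.num) for t in out.terms} == {"u*v", "u_xx"}

    def test_like_terms_are_collected(self):
        expr = SymbolicModel([
            SymbolicTerm("mono", u, None, 0.4),
            SymbolicTerm("mono", u, None, 0.6),
        ])
        out = spf.merge_terms(expr, 1e-2)
        assert len(out.terms) == 1
        assert abs(float(out.terms[0].coeff) - 1.0) < 1e-12

    def test_structural_proper_fraction_is_kept(self):
        # a small proper fraction that did not arise from division must
        # survive for the data to judge
        expr = SymbolicModel([
            SymbolicTerm("mono", u, None, 1.0),
            SymbolicTerm("rational", 1e-4 * u, v**2 + 0.02, 1),
        ])
        out = spf.merge_terms(expr, 1e-2, (0, 0.1), (0, 0.1))
        assert any(t.den is not None for t in out.terms)

    def test_zero_denominator_raises(self):
        expr = SymbolicModel([SymbolicTerm("rational", u, sp.Integer(0), 1)])
        with pytest.raises(ZeroDivisionError):
            spf.merge_terms(expr, 1e-2)


class TestL2Select:
    def _dm(self, theta, labels=None):
        labels = labels or [f"t{i}" for i in range(theta.shape[1])]
        terms = [spf.SparseTerm(l, "mono", sp.Symbol(f"x{i}"))
                 for i, l in enumerate(labels)]
        return spf.DesignMatrix(theta, np.zeros(theta.shape[0]), terms)

    def test_tiny_coefficient_on_orthonormal_columns_removed(self):
        theta = np.eye(4)[:, :2]
        sel = spf.l2_select(self._dm(theta), np.array([1.0, 1e-6]), 0.1)
        assert list(sel.kept) == [0]

    def test_delta_to_zero_keeps_everything(self):
        theta = np.random.default_rng(0).random((20, 5))
        sel = spf.l2_select(self._dm(theta), np.ones(5), 1e-12)
        assert len(sel.kept) == 5

    def test_norm_weighting_rescues_small_coefficients(self):
        # norms (10, 0.1) with xi (0.01, 1): both eta = 0.1, both kept
        theta = np.zeros((2, 2))
        theta[0, 0] = 10.0
        theta[1, 1] = 0.1
        sel = spf.l2_select(self._dm(theta), np.array([0.01, 1.0]), 0.05)
        assert list(sel.kept) == [0, 1]

    def test_scale_equivariance(self, rng):
        theta = rng.random((30, 4))
        xi = rng.normal(size=4)
        sel1 = spf.l2_select(self._dm(theta), xi, 0.2)
        c = 37.0
        theta2 = theta.copy()
        theta2[:, 2] *= c
        xi2 = xi.copy()
        xi2[2] /= c
        sel2 = spf.l2_select(self._dm(theta2), xi2, 0.2)
        assert list(sel1.kept) == list(sel2.kept)

    def test_degenerate_selection_raises(self):
        theta = np.eye(2)
        with pytest.raises(ValueError, match="delta"):
            spf.l2_select(self._dm(theta), np.array([0.0, 0.0]), 0.5)


class TestSTRidge:
    def test_exact_sparse_recovery(self, rng):
        theta = rng.standard_normal((50, 2))
        ut = 3.0 * theta[:, 0]
        xi = spf.stridge(theta, ut, lam=0.0, tol=0.1)
        assert np.isclose(xi[0], 3.0, atol=1e-8)
        assert xi[1] == 0.0

    def test_zero_tolerance_is_plain_ridge(self, rng):
        theta = rng.standard_normal((40, 3))
        ut = rng.standard_normal(40)
        xi = spf.stridge(theta, ut, lam=1e-3, tol=0.0)
        assert np.allclose(xi, spf._ridge(theta, ut, 1e-3))

    def test_overlarge_tolerance_returns_zero_with_warning(self, rng):
        theta = rng.standard_normal((40, 3))
        ut = 0.01 * theta[:, 0]
        with pytest.warns(UserWarning, match="threshold"):
            xi = spf.stridge(theta, ut, lam=0.0, tol=10.0)
        assert np.all(xi == 0.0)

    def test_support_never_grows_back(self, rng):
        theta = rng.standard_normal((100, 6))
        ut = theta[:, 0] - 2 * theta[:, 3] + 0.01 * rng.standard_normal(100)
        xi = spf.stridge(theta, ut, lam=1e-6, tol=0.05)
        support = set(np.flatnonzero(xi))
        assert support <= {0, 3}


class TestDesignMatrix:
    def test_constant_field_gives_constant_column(self, grid1d_small):
        from fracpde.grids import TrajectoryDataset

        uu = np.full((1, 3, grid1d_small.n_points), 2.0)
        ds = TrajectoryDataset(uu, uu.copy(), grid1d_small, 0.05)
        terms = [spf.SparseTerm("u", "mono", u)]
        dm = spf.build_design_matrix(terms, ds)
        assert np.allclose(dm.theta, 2.0)

    def test_duplicate_columns_warn(self, grid1d_small):
        from fracpde.grids import TrajectoryDataset

        rng = np.random.default_rng(0)
        uu = rng.random((1, 3, grid1d_small.n_points))
        ds = TrajectoryDataset(uu, uu.copy(), grid1d_small, 0.05)
        terms = [spf.SparseTerm("u", "mono", u),
                 spf.SparseTerm("u_dup", "mono", u)]
        with pytest.warns(UserWarning, match="rank deficient"):
            spf.build_design_matrix(terms, ds)

    def test_noiseless_regression_recovers_true_coefficients(self):
        # true term set on clean 2-D data: least squares lands near the
        # generating coefficients (time-step and grid bias remain)
        data = dg.make_example_dataset(1, 0.0, seed=2, n_init=3, n_space=64,
                                       sizes=(3, 0, 0))
        tr = data["train"]
        from fracpde.grids import TrajectoryDataset

        # skip the first blocks: the random initial states carry fast
        # high-wavenumber transients that bias forward differences
        tail = TrajectoryDataset(tr.u[:, 8:], tr.v[:, 8:], tr.grid, tr.dt_obs)
        den = np.array([1.0, 0.25, 0.25])
        terms = [
            spf.SparseTerm("1", "mono", sp.Integer(1)),
            spf.SparseTerm("u", "mono", u),
            spf.SparseTerm("lap_u", "diffusion", sp.Symbol("lap_u")),
            spf.SparseTerm("uv/den", "rational", u * v, "u", den, 0),
        ]
        dm = spf.build_design_matrix(terms, tail, field="u")
        xi = spf._ridge(dm.theta, dm.ut, 0.0)
        expect = np.array([1.0, -1.0, 0.3, -0.5])
        assert np.all(np.abs(xi - expect) / np.abs(expect) < 0.15)


class TestSparsifyModel:
    def test_true_support_survives_decoys_on_clean_data(self):
        data = dg.make_example_dataset(1, 0.0, seed=4, n_init=3, n_space=32,
                                       sizes=(3, 0, 0))
        expr = SymbolicModel([
            SymbolicTerm("mono", sp.Integer(1), None, 1.0),
            SymbolicTerm("mono", u, None, -1.0),
            SymbolicTerm("diffusion", sp.Symbol("u_xx"), None, 0.3),
            SymbolicTerm("diffusion", sp.Symbol("u_yy"), None, 0.3),
            SymbolicTerm("rational", -0.5 * u * v,
                         u**2 + 0.25 * u + 0.25, 1),
            # decoys with tiny trained weights
            SymbolicTerm("mono", v, None, 0.003),
            SymbolicTerm("mono", v**2, None, -0.002),
            SymbolicTerm("mono", u * v, None, 0.004),
        ])
        out = spf.sparsify_model(expr, data["train"], field="u", tol=0.05)
        labels = set(out.term_labels())
        assert "lap_u" in labels
        assert "u" in labels and "1" in labels
        assert any("den" in l for l in labels)
        assert "v" not in labels and "v**2" not in labels

    def test_single_term_model_keeps_least_squares_value(self, grid1d_small):
        from fracpde.grids import TrajectoryDataset

        rng = np.random.default_rng(0)
        uu = np.empty((1, 4, grid1d_small.n_points))
        uu[0, 0] = 1 + rng.random(grid1d_small.n_points)
        for k in range(3):
            uu[0, k + 1] = uu[0, k] + 0.05 * (2.0 * uu[0, k])  # u_t = 2u
        ds = TrajectoryDataset(uu, np.ones_like(uu), grid1d_small, 0.05)
        expr = SymbolicModel([SymbolicTerm("mono", u, None, 1.0)])
        out = spf.sparsify_model(expr, ds, field="u", tol=0.01)
        assert len(out.terms) == 1
        assert abs(out.terms[0].coeff - 2.0) < 1e-6


class TestRetrain:
    def test_single_coefficient_matches_closed_form(self, grid1d_small):
        from fracpde.grids import TrajectoryDataset

        rng = np.random.default_rng(3)
        uu = np.empty((2, 4, grid1d_small.n_points))
        uu[:, 0] = 1 + rng.random((2, grid1d_small.n_points))
        c_true = -1.7
        for k in range(3):
            uu[:, k + 1] = uu[:, k] + 0.05 * c_true * uu[:, k]
        ds = TrajectoryDataset(uu, np.ones_like(uu), grid1d_small, 0.05)
        f1 = spf.SparseModel([spf.SparseTerm("u", "mono", u, coeff=0.0)],
                             field="u")
        f2 = spf.SparseModel([spf.SparseTerm("1", "mono", sp.Integer(1),
                                             coeff=0.0)], field="v")
        cfg = LossConfig(0, 0, 0.01, 3, 0.05, teacher_forcing=True)
        r1, _ = spf.retrain_coefficients(f1, f2, ds, cfg, mode="free",
                                         prune_tol=0.0)
        assert abs(r1.terms[0].coeff - c_true) < 1e-6

    def test_retraining_does_not_increase_the_fit_loss(self, tiny_ex2_noisy):
        tr = tiny_ex2_noisy["train"]
        f1 = spf.SparseModel([
            spf.SparseTerm("u", "mono", u, coeff=-0.5),
            spf.SparseTerm("uxx", "diffusion", sp.Symbol("u_xx"), coeff=0.05),
        ], field="u")
        f2 = spf.SparseModel([
            spf.SparseTerm("u", "mono", u, coeff=0.5),
            spf.SparseTerm("v", "mono", v, coeff=-0.2),
        ], field="v")
        cfg = LossConfig(0, 0, 0.01, tr.n_time, 0.05, teacher_forcing=True)

        def fit_loss(m1, m2):
            from fracpde.pipeline import sparse_rhs
            from fracpde import autodiff as ad
            from fracpde.training import generic_rollout_loss

            rhs_np = sparse_rhs(m1, m2, tr.grid)

            def rhs(a, b):
                f, g = rhs_np(a.value, b.value)
                return ad.constant(f), ad.constant(g)

            loss, _ = generic_rollout_loss(rhs, tr, tr.n_time, 0.05, True)
            return float(loss.value)

        before = fit_loss(f1, f2)
        r1, r2 = spf.retrain_coefficients(f1, f2, tr, cfg, mode="free",
                                          prune_tol=0.0)
        after = fit_loss(r1, r2)
        assert after <= before + 1e-9
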
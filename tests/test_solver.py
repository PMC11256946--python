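import numpy as np
import pytest

from adtd.core import naive_hidden_proportion, weighted_nnls
from adtd.model import (ADTDModel, adtd_loss, lambda2_for_group_size,
                        solve_C_subproblem, solve_delta_row,
                        solve_x_subproblem)
from .conftest import elementwise_adtd_loss, tiny_onmodel_instance


def _model_point(rng, p=5, q=2, n=4, delta_spread=0.0):
    """Exact model-generated data with known (C*, x*, Delta*)."""
    X = rng.uniform(0.05, 1.0, (p, q))
    X /= X.sum(axis=0)
    C = rng.uniform(0.05, 0.35, (q, n))
    x = rng.dirichlet(np.ones(p))
    Delta = 1.0 + delta_spread * rng.uniform(-1.0, 1.0, (p, q))
    A = Delta * X
    h = 1.0 - (A @ C).sum(axis=0)
    Y = A @ C + np.outer(x, h)
    return X, Y, C, x, Delta


class TestAdtdLoss:
    def test_zero_at_exact_model_point_without_penalties(self):
        X, Y, C, x, Delta = _model_point(np.random.default_rng(0),
                                         delta_spread=0.3)
        g = np.random.default_rng(1).uniform(0.2, 1.0, X.shape[0])
        assert adtd_loss(C, x, Delta, X, Y, g, 0.0, 0.0, C) == \
            pytest.approx(0.0, abs=1e-18)

    def test_all_ones_delta_zeroes_the_delta_penalty(self):
        X, Y, C, x, _ = _model_point(np.random.default_rng(2))
        g = np.ones(X.shape[0])
        ones = np.ones_like(X)
        base = adtd_loss(C, x, ones, X, Y, g, 0.0, 0.0, C)
        assert adtd_loss(C, x, ones, X, Y, g, 0.0, 1e6, C) == \
            pytest.approx(base, abs=1e-12)

    def test_matches_elementwise_recomputation(self):
        rng = np.random.default_rng(3)
        p, q, n = 4, 2, 3
        X = rng.uniform(0.1, 1.0, (p, q)); X /= X.sum(axis=0)
        Y = rng.uniform(0.1, 1.0, (p, n)); Y /= Y.sum(axis=0)
        C = rng.uniform(0.0, 0.6, (q, n))
        C0 = rng.uniform(0.0, 0.6, (q, n))
        x = rng.dirichlet(np.ones(p))
        Delta = rng.uniform(0.3, 2.0, (p, q))
        g = rng.uniform(0.1, 1.0, p)
        expected = elementwise_adtd_loss(C, x, Delta, X, Y, g, 0.17, 0.03, C0)
        assert adtd_loss(C, x, Delta, X, Y, g, 0.17, 0.03, C0) == \
            pytest.approx(expected, rel=1e-12)

    def test_infinite_penalties_contribute_nothing(self):
        X, Y, C, x, Delta = _model_point(np.random.default_rng(4))
        g = np.ones(X.shape[0])
        finite = adtd_loss(C, x, np.ones_like(X), X, Y, g, 0.0, 0.0, C)
        assert adtd_loss(C, x, np.ones_like(X), X, Y, g, np.inf, np.inf, C) \
            == pytest.approx(finite, abs=1e-15)


class TestCSubproblem:
    def test_huge_anchor_returns_projected_naive(self):
        rng = np.random.default_rng(5)
        X, Y, C, x, _ = _model_point(rng, n=5)
        g = rng.uniform(0.3, 1.0, X.shape[0])
        C0 = weighted_nnls(X, Y, g**2)
        assert (X @ C0).sum(axis=0).max() < 1.0  # premise: budget slack
        C_hat = solve_C_subproblem(Y, X, x, g, 1e12, C0)
        np.testing.assert_allclose(C_hat, C0, atol=1e-4)

    def test_noiseless_fully_explained_bulk_has_zero_background(self):
        rng = np.random.default_rng(6)
        p, q, n = 6, 2, 4
        X = rng.uniform(0.05, 1.0, (p, q)); X /= X.sum(axis=0)
        C_true = rng.dirichlet(np.ones(q), size=n).T  # colsum exactly 1
        Y = X @ C_true
        g = np.full(p, 1.0 / np.sqrt(p))
        x = rng.dirichlet(np.ones(p))
        C_hat = solve_C_subproblem(Y, X, x, g, 1e-6, C_true)
        h = 1.0 - (X @ C_hat).sum(axis=0)
        np.testing.assert_allclose(h, 0.0, atol=1e-6)

    def test_matches_grid_search_oracle_q2(self):
        rng = np.random.default_rng(7)
        p, n = 4, 1
        X = rng.uniform(0.1, 1.0, (p, 2)); X /= X.sum(axis=0)
        y = rng.uniform(0.1, 1.0, p); y /= y.sum()
        x = rng.dirichlet(np.ones(p))
        g = rng.uniform(0.3, 1.0, p)
        C0 = rng.uniform(0.0, 0.5, (2, 1))
        lam1 = 0.05
        c_hat = solve_C_subproblem(y[:, None], X, x, g, lam1, C0)[:, 0]

        a = X.sum(axis=0)
        grid = np.linspace(0.0, 1.2, 1201)
        c1, c2 = np.meshgrid(grid, grid, indexing="ij")
        feas = a[0] * c1 + a[1] * c2 <= 1.0 + 1e-12

        def obj(v1, v2):
            h = 1.0 - (a[0] * v1 + a[1] * v2)
            R = (y[:, None, None] - np.einsum("p,ij->pij", X[:, 0], v1)
                 - np.einsum("p,ij->pij", X[:, 1], v2)
                 - np.einsum("p,ij->pij", x, h))
            return (np.einsum("p,pij->ij", g**2, R**2)
                    + lam1 * ((v1 - C0[0, 0])**2 + (v2 - C0[1, 0])**2))

        vals = np.where(feas, obj(c1, c2), np.inf)
        best_grid = float(vals.min())
        h_hat = 1.0 - float(a @ c_hat)
        r = g * (y - X @ c_hat - x * h_hat)
        obj_hat = float(r @ r) + lam1 * float(((c_hat - C0[:, 0])**2).sum())
        assert obj_hat <= best_grid + 1e-6

    def test_infinite_anchor_is_rejected(self):
        X = np.ones((3, 1)) / 3.0
        with pytest.raises(ValueError):
            solve_C_subproblem(np.ones((3, 1)), X, np.ones(3) / 3,
                               np.ones(3), np.inf, np.ones((1, 1)))


class TestXSubproblem:
    def test_single_sample_zero_composition_copies_bulk(self):
        rng = np.random.default_rng(8)
        p = 6
        y = rng.dirichlet(np.ones(p))
        X = rng.uniform(0.1, 1.0, (p, 2)); X /= X.sum(axis=0)
        x = solve_x_subproblem(y[:, None], X, np.zeros((2, 1)),
                               rng.uniform(0.2, 1.0, p))
        np.testing.assert_allclose(x, y, atol=1e-10)

    def test_recovers_shared_background_noiseless(self):
        rng = np.random.default_rng(9)
        X, Y, C, x_true, _ = _model_point(rng, p=7, q=2, n=3)
        x_hat = solve_x_subproblem(Y, X, C, rng.uniform(0.2, 1.0, 7))
        np.testing.assert_allclose(x_hat, x_true, atol=1e-6)

    def test_unidentifiable_background_warns_and_returns_uniform(self):
        rng = np.random.default_rng(10)
        p, q, n = 5, 2, 3
        X = rng.uniform(0.1, 1.0, (p, q)); X /= X.sum(axis=0)
        C = np.tile(rng.dirichlet(np.ones(q))[:, None], (1, n))  # colsum 1
        Y = X @ C
        with pytest.warns(RuntimeWarning, match="unidentifiable"):
            x = solve_x_subproblem(Y, X, C, np.ones(p))
        np.testing.assert_allclose(x, np.full(p, 1.0 / p))


class TestDeltaRow:
    def test_huge_penalty_returns_all_ones(self):
        rng = np.random.default_rng(11)
        X, Y, C, x, _ = _model_point(rng, delta_spread=0.4)
        g = rng.uniform(0.2, 1.0, X.shape[0])
        row = solve_delta_row(2, Y, X, C, x, g, 1e12, np.ones_like(X))
        np.testing.assert_allclose(row, 1.0, atol=1e-4)

    def test_single_celltype_matches_parabola_vertex(self):
        """With q=1 the row problem is a scalar quadratic; the minimizer
        must match the vertex of a parabola fitted through three loss
        evaluations (clamped at zero)."""
        rng = np.random.default_rng(12)
        p, n = 4, 3
        X = rng.uniform(0.1, 1.0, (p, 1)); X /= X.sum(axis=0)
        C = rng.uniform(0.2, 0.8, (1, n))
        x = rng.dirichlet(np.ones(p))
        Y = rng.uniform(0.05, 0.5, (p, n))
        g = rng.uniform(0.2, 1.0, p)
        lam2 = 0.01
        k = 1
        Delta = np.ones((p, 1))

        def f(d):
            D = Delta.copy()
            D[k, 0] = d
            return elementwise_adtd_loss(C, x, D, X, Y, g, 0.0, lam2,
                                         np.zeros_like(C))

        f0, f1, f2 = f(0.0), f(1.0), f(2.0)
        aa = (f0 - 2 * f1 + f2) / 2.0
        bb = (f2 - f0) / 2.0
        vertex = max(0.0, 1.0 - bb / (2.0 * aa))
        row = solve_delta_row(k, Y, X, C, x, g, lam2, Delta)
        assert row[0] == pytest.approx(vertex, abs=1e-8)

    def test_recovers_spiked_factor_on_exclusive_gene(self):
        """Given the true compositions and background, the row update
        recovers a known multiplicative spike on a gene expressed by a
        single cell type (a spike on one exclusive gene is confounded
        with the background in the *joint* problem, so the row operation
        is validated at the generative parameters)."""
        rng = np.random.default_rng(13)
        p, q, n = 30, 2, 80
        X = rng.uniform(0.05, 1.0, (p, q))
        X[0, 1] = 0.0  # gene 0 expressed by type 0 only
        X /= X.sum(axis=0)
        Delta_true = np.ones((p, q))
        Delta_true[0, 0] = 3.0  # a = +2
        C = rng.uniform(0.1, 0.4, (q, n))
        A = Delta_true * X
        x_true = rng.dirichlet(np.ones(p))
        h = 1.0 - (A @ C).sum(axis=0)
        Y = A @ C + np.outer(x_true, h)
        g = np.full(p, 1.0 / np.sqrt(p))
        row = solve_delta_row(0, Y, X, C, x_true, g, 1e-8, np.ones((p, q)))
        assert row[0] == pytest.approx(3.0, rel=0.05)
        assert row[1] == pytest.approx(1.0, rel=0.05)


class TestFit:
    def test_naive_limit_reproduces_weighted_nnls_and_eq7(self):
        rng = np.random.default_rng(14)
        X, Y, *_ = _model_point(rng, p=20, q=3, n=12)
        g = rng.uniform(0.2, 1.0, 20)
        g /= np.linalg.norm(g)
        C0 = weighted_nnls(X, Y / Y.sum(axis=0), g**2)
        assert (X @ C0).sum(axis=0).max() < 1.0  # premise: budget slack
        res = ADTDModel(Y, X, gene_weights=g, lambda1=1e12,
                        adapt_reference=False).fit()
        np.testing.assert_allclose(res.C, C0, atol=1e-3)
        np.testing.assert_allclose(res.hidden_weights,
                                   naive_hidden_proportion(C0), atol=1e-3)

    def test_hard_constraint_mode_fixes_C_exactly(self):
        rng = np.random.default_rng(15)
        X, Y, *_ = _model_point(rng, p=10, q=2, n=5)
        g = np.full(10, 1.0 / np.sqrt(10))
        res = ADTDModel(Y, X, gene_weights=g, lambda1=np.inf,
                        adapt_reference=False).fit()
        np.testing.assert_array_equal(res.C, res.C0)

    def test_frozen_delta_limit(self):
        rng = np.random.default_rng(16)
        X, Y, *_ = _model_point(rng, p=10, q=2, n=6)
        res = ADTDModel(Y, X, lambda2=1e12).fit()
        assert np.abs(res.Delta - 1.0).max() < 1e-3

    def test_monotone_loss_and_constraints(self, study_fixture):
        res = study_fixture["result"]
        losses = [v for _, v in res.block_loss_trace]
        tol = 10 * 1e-7
        for a, b in zip(losses, losses[1:]):
            assert b <= a + tol * max(1.0, abs(a))
        report = res.constraint_report()
        assert report["min_C"] >= -1e-6
        assert report["min_x"] >= -1e-6
        assert abs(report["sum_x_minus_1"]) <= 1e-6
        assert report["min_Delta"] >= -1e-6
        assert report["max_budget"] <= 1.0 + 1e-6

    def test_gene_and_sample_permutation_equivariance(self):
        rng = np.random.default_rng(17)
        X, Y, *_ = _model_point(rng, p=12, q=2, n=6, delta_spread=0.2)
        kw = dict(lambda1=0.05, lambda2=1e-4, max_iter=400, tol=1e-11)
        base = ADTDModel(Y, X, **kw).fit()
        # gene permutation also permutes the Gauss-Seidel row-sweep order,
        # so the fixed points agree only to solver tolerance
        pg = rng.permutation(12)
        perm_g = ADTDModel(Y[pg], X[pg], **kw).fit()
        np.testing.assert_allclose(perm_g.C, base.C, atol=1e-3)
        np.testing.assert_allclose(perm_g.x, base.x[pg], atol=1e-3)
        np.testing.assert_allclose(perm_g.Delta, base.Delta[pg], atol=1e-2)
        ps = rng.permutation(6)
        perm_s = ADTDModel(Y[:, ps], X, **kw).fit()
        np.testing.assert_allclose(perm_s.C, base.C[:, ps], atol=1e-6)
        np.testing.assert_allclose(perm_s.x, base.x, atol=1e-6)

    def test_null_regulation_keeps_delta_near_one(self):
        rng = np.random.default_rng(18)
        X, Y, C, x_true, _ = _model_point(rng, p=25, q=3, n=40)
        res = ADTDModel(Y, X, lambda1=0.0, lambda2=1e-4, max_iter=500,
                        tol=1e-10).fit()
        assert np.abs(res.Delta - 1.0).max() < 1e-2

    def test_tiny_penalties_trigger_overfitting_warning(self):
        rng = np.random.default_rng(19)
        X, Y, *_ = _model_point(rng)
        with pytest.warns(UserWarning, match="overfit"):
            ADTDModel(Y, X, lambda1=1e-9, lambda2=1e-9)

    def test_group_size_scaled_delta_penalty(self):
        assert lambda2_for_group_size(1000) == pytest.approx(1e-5)
        assert lambda2_for_group_size(190, base=1e-5) == \
            pytest.approx(1e-5 * 0.19)

    def test_summary_reports_dimensions_and_loss(self, study_fixture):
        text = study_fixture["result"].summary()
        assert "genes: 200" in text
        assert "lambda1" in text
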
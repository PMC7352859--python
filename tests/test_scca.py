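"""Sparse CCA: feasibility, oracles, discrimination behavior."""

import numpy as np
import pytest
from scipy import optimize

from bioperturb import (
    canonical_coefficients,
    encode_groups,
    fit_scca,
    scca_discriminant_roc,
    vector_projection,
)
from bioperturb.scca import _project


def standardize(X):
    return (X - X.mean(axis=0)) / X.std(axis=0, ddof=1)


def orthonormal_design(rng, n, p):
    """Standardized X with exactly orthogonal columns."""
    X = rng.standard_normal((n, p))
    X = X - X.mean(axis=0)
    q, _ = np.linalg.qr(X)
    q = q - q.mean(axis=0)
    return q / q.std(axis=0, ddof=1)


class TestProjection:
    def test_no_sparsity_is_normalization(self):
        c = np.array([3.0, -4.0])
        u = _project(c, budget=np.sqrt(2))
        assert np.allclose(u, c / 5.0)

    def test_budget_one_selects_single_coordinate(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c = rng.standard_normal(6)
            u = _project(c, budget=1.0)
            nz = np.flatnonzero(np.abs(u) > 1e-8)
            assert len(nz) == 1
            assert nz[0] == np.argmax(np.abs(c))

    def test_feasibility(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            c = rng.standard_normal(8)
            budget = rng.uniform(1.0, np.sqrt(8))
            u = _project(c, budget)
            assert np.linalg.norm(u) <= 1.0 + 1e-9
            assert np.abs(u).sum() <= budget + 1e-6


class TestFit:
    def test_perfect_correlation(self):
        # Y duplicates X: two identical standardized columns on each side
        rng = np.random.default_rng(2)
        z = standardize(rng.standard_normal((30, 1)))
        X = np.hstack([z, z])
        Y = np.hstack([z, z])
        m = fit_scca(X, Y, penalty_u=np.sqrt(2), penalty_v=np.sqrt(2))
        assert m.canonical_correlation == pytest.approx(1.0, abs=1e-6)

    def test_penalty_one_single_marker(self, panel):
        from bioperturb import log10_zscore
        X = log10_zscore(panel).values.to_numpy()
        Y = encode_groups(panel.steatosis.to_numpy())
        m = fit_scca(X, Y, penalty_u=1.0)
        nz = np.flatnonzero(np.abs(m.u) > 1e-8)
        assert len(nz) == 1
        # the selected coordinate maximizes the rank-1 objective: verify by
        # enumeration over single-marker fits
        Z = X.T @ Y
        best = np.argmax(np.linalg.norm(Z, axis=1))
        assert nz[0] == best

    def test_objective_matches_constrained_optimizer(self):
        # brute-force oracle: SLSQP maximization of u'Zv over the feasible
        # set, from several starts, on small problems
        rng = np.random.default_rng(3)
        for trial in range(5):
            X = standardize(rng.standard_normal((25, 3)))
            Y = encode_groups(rng.integers(0, 2, 25))
            if len(np.unique(Y[:, 0])) < 2:
                continue
            pu, pv = 1.2, np.sqrt(2)
            m = fit_scca(X, Y, penalty_u=pu, penalty_v=pv)
            Z = X.T @ Y

            def neg_obj(w):
                return -(w[:3] @ Z @ w[3:])

            cons = [
                {"type": "ineq", "fun": lambda w: 1 - np.sum(w[:3] ** 2)},
                {"type": "ineq", "fun": lambda w: 1 - np.sum(w[3:] ** 2)},
                {"type": "ineq", "fun": lambda w: pu - np.abs(w[:3]).sum()},
                {"type": "ineq", "fun": lambda w: pv - np.abs(w[3:]).sum()},
            ]
            best = -np.inf
            for s in range(8):
                w0 = rng.standard_normal(5) * 0.3
                res = optimize.minimize(neg_obj, w0, method="SLSQP",
                                        constraints=cons,
                                        options={"maxiter": 300})
                if res.success:
                    best = max(best, -res.fun)
            assert m.objective >= best - 1e-4

    def test_matches_classical_cca_without_sparsity(self):
        # with orthonormal X columns and no L1 activity, the rank-1 fit's
        # canonical correlation equals the classical canonical correlation,
        # which for a binary outcome is sqrt(R^2) of the OLS projection
        rng = np.random.default_rng(4)
        for _ in range(5):
            X = orthonormal_design(rng, 40, 5)
            y = rng.integers(0, 2, 40)
            if len(np.unique(y)) < 2:
                continue
            m = fit_scca(X, encode_groups(y), penalty_u=np.sqrt(5),
                         penalty_v=np.sqrt(2))
            yc = y - y.mean()
            beta = np.linalg.lstsq(X, yc, rcond=None)[0]
            r2 = 1 - np.sum((yc - X @ beta) ** 2) / np.sum(yc ** 2)
            assert abs(m.canonical_correlation) == pytest.approx(
                np.sqrt(r2), abs=1e-4)

    def test_feasibility_and_correlation_invariants(self, panel):
        from bioperturb import log10_zscore
        X = log10_zscore(panel).values.to_numpy()
        Y = encode_groups(panel.steatosis.to_numpy())
        m = fit_scca(X, Y)
        assert np.linalg.norm(m.u) <= 1 + 1e-6
        assert np.linalg.norm(m.v) <= 1 + 1e-6
        assert np.abs(m.u).sum() <= m.penalty_u + 1e-6
        assert np.abs(m.v).sum() <= m.penalty_v + 1e-6
        ccor = np.corrcoef(X @ m.u, Y @ m.v)[0, 1]
        assert m.canonical_correlation == pytest.approx(ccor, abs=1e-6)

    def test_unstandardized_rejected(self, panel):
        with pytest.raises(ValueError, match="standardized"):
            fit_scca(panel.markers.to_numpy(),
                     encode_groups(panel.steatosis.to_numpy()))
        with pytest.raises(ValueError, match="penalties"):
            fit_scca(np.zeros((4, 2)), np.zeros((4, 2)), penalty_u=0.5)

    def test_all_zero_degenerate(self):
        m = fit_scca(np.zeros((10, 3)), np.zeros((10, 2)))
        assert m.degenerate
        assert np.all(m.u == 0)


class TestCoefficientsAndROC:
    def test_ranking_invariant_to_column_order(self, panel):
        from bioperturb import log10_zscore
        X = log10_zscore(panel).values.to_numpy()
        Y = encode_groups(panel.steatosis.to_numpy())
        m1 = fit_scca(X, Y, marker_names=panel.marker_names)
        perm = np.random.default_rng(8).permutation(X.shape[1])
        m2 = fit_scca(X[:, perm], Y,
                      marker_names=[panel.marker_names[i] for i in perm])
        r1 = canonical_coefficients(m1)
        r2 = canonical_coefficients(m2)
        top1 = set(r1.loc[r1.abs_weight > 1e-6, "marker"].head(5))
        top2 = set(r2.loc[r2.abs_weight > 1e-6, "marker"].head(5))
        assert top1 == top2

    def test_perfectly_separated_scores_auc_one(self):
        rng = np.random.default_rng(9)
        y = np.array([0] * 15 + [1] * 15)
        X = standardize(rng.standard_normal((30, 3)))
        X[:, 0] = standardize((y * 10.0 + np.arange(30) * 0.01)[:, None])[:, 0]
        roc, model = scca_discriminant_roc(X, y)
        assert roc.auc == pytest.approx(1.0)

    def test_label_permutation_auc_near_half(self, panel):
        from bioperturb import log10_zscore
        X = log10_zscore(panel).values.to_numpy()
        y = np.random.default_rng(10).permutation(panel.steatosis.to_numpy())
        roc, _ = scca_discriminant_roc(X, y)
        assert 0.4 <= roc.auc <= 0.75  # resubstitution optimism allowed

    def test_resubstitution_at_least_loo_on_average(self):
        rng = np.random.default_rng(11)
        diffs = []
        for seed in range(5):
            y = np.array([0] * 15 + [1] * 15)
            X = rng.standard_normal((30, 6))
            X[:, 0] += y * 0.8
            Xs = standardize(X)
            r_res, _ = scca_discriminant_roc(Xs, y, mode="resubstitution")
            r_loo, _ = scca_discriminant_roc(Xs, y, mode="loo_cv")
            diffs.append(r_res.auc - r_loo.auc)
        assert np.mean(diffs) >= -0.02

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            scca_discriminant_roc(np.zeros((5, 2)), np.zeros(5, dtype=int))


class TestVectorProjection:
    def test_two_group_outcome_second_pair_degenerate(self, panel):
        from bioperturb import log10_zscore
        X = log10_zscore(panel).values.to_numpy()
        Y = encode_groups(panel.steatosis.to_numpy())
        coords, vectors, model, degenerate2 = vector_projection(
            X, Y, marker_names=panel.marker_names)
        assert degenerate2
        assert coords.shape == (panel.n_samples, 2)

    def test_marker_identical_to_variate_has_unit_vector(self):
        rng = np.random.default_rng(12)
        y = np.array([0] * 20 + [1] * 20)
        X = standardize(rng.standard_normal((40, 3)))
        X[:, 0] = standardize((y.astype(float))[:, None])[:, 0]
        coords, vectors, model, _ = vector_projection(
            X, encode_groups(y), penalty_u=1.0)
        assert abs(vectors.iloc[0, 0]) == pytest.approx(1.0, abs=1e-9)

    def test_bitwise_reproducible(self, panel):
        from bioperturb import log10_zscore
        X = log10_zscore(panel).values.to_numpy()
        Y = encode_groups(panel.steatosis.to_numpy())
        c1, v1, _, _ = vector_projection(X, Y)
        c2, v2, _, _ = vector_projection(X, Y)
        assert np.array_equal(c1.to_numpy(), c2.to_numpy())
        assert np.array_equal(v1.to_numpy(), v2.to_numpy())
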
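"""Nonparametric tests against brute-force oracles and hand calculations."""

import itertools

import numpy as np
import pytest
from scipy import stats

from bioperturb import (
    chi_square,
    cuzick_trend,
    fold_differences,
    holm_adjust,
    kruskal_wallis_dunn,
    mann_whitney,
    roc_curve,
)
from conftest import toy_panel


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------

def exact_mw_p(x, y):
    """Two-sided Mann-Whitney p by full enumeration of group assignments."""
    pooled = np.concatenate([x, y])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    obs = ranks[:len(x)].sum()
    null = [sum(ranks[list(c)]) for c in itertools.combinations(range(n), len(x))]
    null = np.asarray(null)
    mean = null.mean()
    return np.mean(np.abs(null - mean) >= abs(obs - mean) - 1e-12)


def holm_bruteforce(p):
    """Step-down Holm from first principles."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running = 0.0
    for i, idx in enumerate(order):
        val = min((m - i) * p[idx], 1.0)
        running = max(running, val)
        adj[idx] = running
    return adj


class TestMannWhitney:
    def test_separated_samples_exact(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0
        assert res.p_raw == pytest.approx(0.1)  # 2 / C(6,3)
        assert res.extra["exact"]

    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.p_raw == pytest.approx(1.0, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1.0])

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            nx = rng.integers(2, 6)
            ny = rng.integers(2, 7 - max(0, nx - 5))
            x = rng.standard_normal(nx)
            y = rng.standard_normal(ny)
            res = mann_whitney(x, y)
            assert res.p_raw == pytest.approx(exact_mw_p(x, y), abs=1e-12)

    def test_approximate_close_to_exact_small_n(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            x = rng.standard_normal(6)
            y = rng.standard_normal(6)
            exact = mann_whitney(x, y).p_raw
            approx = mann_whitney(x, y, exact_max_n=0).p_raw
            assert abs(exact - approx) < 0.03

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(1, 10, 15)
        y = rng.uniform(1, 10, 20)
        a = mann_whitney(x, y)
        b = mann_whitney(np.log(x), np.log(y))
        assert a.statistic == b.statistic
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_auc_identity_with_roc(self):
        rng = np.random.default_rng(9)
        for _ in range(20):
            x = rng.standard_normal(8)   # cases
            y = rng.standard_normal(11)  # controls
            res = mann_whitney(x, y)
            scores = np.concatenate([x, y])
            labels = np.array([1] * 8 + [0] * 11)
            auc = roc_curve(scores, labels).auc
            assert auc == pytest.approx(res.extra["u_x"] / (8 * 11), abs=1e-12)


class TestKruskalDunn:
    def test_identical_groups(self):
        overall, pairs = kruskal_wallis_dunn([[1, 2], [1, 2], [1, 2]])
        assert overall.statistic == pytest.approx(0.0, abs=1e-9)
        assert all(p.p_raw > 0.9 for p in pairs)

    def test_extreme_pair_has_smallest_p(self):
        overall, pairs = kruskal_wallis_dunn([[1, 2], [3, 4], [100, 101]],
                                             labels=["a", "b", "c"])
        by_pair = {p.extra["pair"]: p.p_raw for p in pairs}
        assert by_pair[("a", "c")] == min(by_pair.values())

    def test_two_groups_redirects(self):
        with pytest.raises(ValueError, match="mann_whitney"):
            kruskal_wallis_dunn([[1, 2], [3, 4]])

    def test_chi_square_approx_close_to_permutation(self):
        # exhaustive permutation p over the 1680 distinct 3/3/3 partitions
        rng = np.random.default_rng(11)
        data = rng.standard_normal(9)
        groups = [data[:3], data[3:6], data[6:]]
        ranks = stats.rankdata(data)

        def h_of(assign):
            # tie-free H from rank sums
            n = 9
            h = 0.0
            for g in range(3):
                r = ranks[[i for i, a in enumerate(assign) if a == g]]
                h += r.sum() ** 2 / 3
            return 12 / (n * (n + 1)) * h - 3 * (n + 1)

        h_obs = h_of([0] * 3 + [1] * 3 + [2] * 3)
        null = []
        idx = set(range(9))
        for g0 in itertools.combinations(range(9), 3):
            rest = idx - set(g0)
            for g1 in itertools.combinations(sorted(rest), 3):
                assign = np.empty(9, dtype=int)
                assign[list(g0)] = 0
                assign[list(g1)] = 1
                assign[list(rest - set(g1))] = 2
                null.append(h_of(assign))
        p_perm = np.mean(np.asarray(null) >= h_obs - 1e-12)
        p_approx = kruskal_wallis_dunn(groups)[0].p_raw
        assert abs(p_perm - p_approx) < 0.05


class TestCuzickTrend:
    def test_monotone_direction(self):
        res = cuzick_trend([[1, 2], [3, 4], [5, 6]])
        assert res.statistic > 0
        assert res.p_raw < 0.05

    def test_reversal_antisymmetry(self):
        groups = [[1, 5, 2], [3, 4], [6, 9, 7]]
        a = cuzick_trend(groups)
        b = cuzick_trend(groups[::-1])
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_raw == pytest.approx(b.p_raw)

    def test_constant_data(self):
        res = cuzick_trend([[2, 2], [2, 2], [2, 2]])
        assert res.statistic == 0.0
        assert res.p_raw == 1.0

    def test_close_to_permutation_monte_carlo(self):
        rng = np.random.default_rng(21)
        groups = [rng.standard_normal(8) + 0.3 * i for i in range(3)]
        res = cuzick_trend(groups)
        pooled = np.concatenate(groups)
        a = np.concatenate([np.full(len(g), s) for g, s in
                            zip(groups, [0.0, 1.0, 2.0])])
        ranks = stats.rankdata(pooled)
        t_obs = float(np.sum(a * ranks))
        e_t = len(pooled) * a.mean() * ranks.mean()
        n_perm = 100_000
        perm_t = np.empty(n_perm)
        for i in range(n_perm):
            perm_t[i] = np.sum(a * rng.permutation(ranks))
        p_mc = np.mean(np.abs(perm_t - e_t) >= abs(t_obs - e_t) - 1e-9)
        assert abs(res.p_raw - p_mc) < 0.02


class TestChiSquare:
    def test_perfect_association_closed_form(self):
        # 2x2 closed form n(ad-bc)^2/(r1 r2 c1 c2)
        res = chi_square([[10, 0], [0, 10]])
        assert res.statistic == pytest.approx(20.0)

    def test_no_association(self):
        res = chi_square([[5, 5], [5, 5]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_raw == pytest.approx(1.0)
        res = chi_square([[18, 18], [18, 18]])
        assert res.statistic == pytest.approx(0.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square([[0, 0], [5, 5]])


class TestHolm:
    def test_hand_example(self):
        adj = holm_adjust([0.01, 0.04, 0.03])
        assert np.allclose(adj, [0.03, 0.06, 0.06])

    def test_single_and_degenerate(self):
        assert holm_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(holm_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            holm_adjust([0.5, 1.5])

    def test_matches_bruteforce_on_random_vectors(self):
        rng = np.random.default_rng(5)
        for _ in range(1000):
            m = rng.integers(1, 12)
            p = rng.uniform(size=m)
            assert np.allclose(holm_adjust(p), holm_bruteforce(p), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        for _ in range(20):
            p = rng.uniform(size=rng.integers(1, 30))
            assert np.allclose(holm_adjust(p),
                               multipletests(p, method="holm")[1], atol=1e-12)

    def test_adjusted_at_least_raw_and_monotone(self):
        rng = np.random.default_rng(6)
        p = rng.uniform(size=25)
        adj = holm_adjust(p)
        assert np.all(adj >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(adj[order]) >= -1e-15)


class TestFoldDifferences:
    def test_hand_fold(self):
        p = toy_panel({"A": [10, 10, 10, 20, 20, 20]},
                      steatosis=[0, 0, 0, 1, 1, 1])
        fd = fold_differences(p)[0]
        assert fd.fold == pytest.approx(2.0)
        assert fd.log2_fold == pytest.approx(1.0)

    def test_identical_groups_not_significant(self):
        p = toy_panel({"A": [1, 2, 3, 1, 2, 3]}, steatosis=[0, 0, 0, 1, 1, 1])
        fd = fold_differences(p)[0]
        assert fd.fold == pytest.approx(1.0)
        assert not fd.significant

    def test_fold_equals_power_of_median_log_difference(self, panel):
        for fd in fold_differences(panel):
            cases = np.log10(panel.markers[fd.marker][panel.case_mask])
            controls = np.log10(panel.markers[fd.marker][panel.control_mask])
            expected = 10 ** (np.median(cases) - np.median(controls))
            assert fd.fold == pytest.approx(expected, rel=1e-9)
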
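"""Nonparametric group comparisons, trend tests and multiplicity control.

The panel data are treated as non-Gaussian throughout: two-group
comparisons use the Mann-Whitney U test, multi-group comparisons the
Kruskal-Wallis test with Dunn's pairwise post-hoc z-tests and a
Wilcoxon-type (Cuzick) nonparametric linear trend test across ordered
severity grades, and proportions the Pearson chi-square test. Family-wise
error over the marker panel is controlled with the Holm-Bonferroni
step-down procedure. Fold differences are ratios of group medians on the
native concentration scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .panel import BiomarkerPanel


@dataclass
class TestResult:
    marker: str
    method: str
    statistic: float
    p_raw: float
    p_adjusted: float | None = None
    group_medians: dict = field(default_factory=dict)  # label -> (median, q1, q3)
    extra: dict = field(default_factory=dict)


@dataclass
class FoldDifference:
    marker: str
    fold: float          # case median / control median, native scale
    log2_fold: float
    p_raw: float
    p_adjusted: float
    significant: bool    # Holm-adjusted p < 0.05


def _median_iqr(x) -> tuple[float, float, float]:
    x = np.asarray(x, dtype=float)
    return (float(np.median(x)), float(np.percentile(x, 25)),
            float(np.percentile(x, 75)))


def mann_whitney(x, y, continuity: bool = True,
                 exact_max_n: int = 12) -> TestResult:
    """Two-sided Mann-Whitney U test.

    Exact p by enumeration when the pooled sample has no ties and at most
    ``exact_max_n`` observations; otherwise the normal approximation with
    tie correction and (by default) continuity correction. The reported
    statistic is min(U_x, U_y).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney requires two non-empty samples")
    pooled = np.concatenate([x, y])
    ties = len(np.unique(pooled)) < len(pooled)
    if not ties and len(pooled) <= exact_max_n:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=continuity)
    u_x = float(res.statistic)
    u_y = len(x) * len(y) - u_x
    return TestResult(
        marker="", method="mann_whitney", statistic=min(u_x, u_y),
        p_raw=float(min(res.pvalue, 1.0)),
        group_medians={"x": _median_iqr(x), "y": _median_iqr(y)},
        extra={"u_x": u_x, "u_y": u_y, "exact": method == "exact"},
    )


def kruskal_wallis_dunn(groups, labels=None,
                        adjust: str = "holm") -> tuple[TestResult, list[TestResult]]:
    """Kruskal-Wallis H test with Dunn's pairwise post-hoc z-tests.

    Dunn z-statistics use the pooled mid-ranks with the standard tie
    correction; pairwise p-values are adjusted within the pairwise family
    (``holm`` by default, also ``bonferroni`` or ``none``).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("kruskal_wallis_dunn needs >=3 groups; use mann_whitney")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    if labels is None:
        labels = [str(i) for i in range(len(groups))]

    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        h, p = 0.0, 1.0
    else:
        h, p = stats.kruskal(*groups)
    overall = TestResult(
        marker="", method="kruskal_wallis", statistic=float(h), p_raw=float(p),
        group_medians={lab: _median_iqr(g) for lab, g in zip(labels, groups)},
    )

    ranks = stats.rankdata(pooled)
    n = len(pooled)
    sizes = [len(g) for g in groups]
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i]:bounds[i + 1]].mean() for i in range(len(groups))]
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts ** 3 - counts)) / (12.0 * (n - 1)) if n > 1 else 0.0
    var_base = n * (n + 1) / 12.0 - tie_term

    pairwise = []
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
            z = 0.0 if se == 0 else (mean_ranks[i] - mean_ranks[j]) / se
            p_ij = 1.0 if se == 0 else 2.0 * stats.norm.sf(abs(z))
            pairwise.append(TestResult(
                marker="", method="dunn_pairwise", statistic=float(z),
                p_raw=float(min(p_ij, 1.0)),
                extra={"pair": (labels[i], labels[j])},
            ))
    if adjust != "none" and pairwise:
        adj = multipletests([r.p_raw for r in pairwise], method=adjust)[1]
        for r, a in zip(pairwise, adj):
            r.p_adjusted = float(a)
    return overall, pairwise


def cuzick_trend(groups, scores=None) -> TestResult:
    """Cuzick's Wilcoxon-type nonparametric test for trend across ordered groups.

    The statistic T = sum_j score(group_j) * rank_j is standardized by its
    exact permutation mean and variance (mid-ranks handle ties), giving a
    two-sided normal p. The sign of z reports the trend direction relative
    to the supplied ordinal group scores (default 0, 1, 2, ...).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 3:
        raise ValueError("cuzick_trend needs >=3 ordered groups")
    if scores is None:
        scores = np.arange(len(groups), dtype=float)
    scores = np.asarray(scores, dtype=float)

    pooled = np.concatenate(groups)
    a = np.concatenate([np.full(len(g), s) for g, s in zip(groups, scores)])
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    t_stat = float(np.sum(a * ranks))
    e_t = n * a.mean() * ranks.mean()
    # exact permutation variance of a linear rank statistic
    var_t = (np.sum((a - a.mean()) ** 2) * np.sum((ranks - ranks.mean()) ** 2)
             / (n - 1))
    if var_t <= 0:
        z, p = 0.0, 1.0
    else:
        z = (t_stat - e_t) / np.sqrt(var_t)
        p = 2.0 * stats.norm.sf(abs(z))
    return TestResult(marker="", method="cuzick_trend", statistic=float(z),
                      p_raw=float(min(p, 1.0)), extra={"T": t_stat})


def chi_square(table) -> TestResult:
    """Pearson chi-square test on a 2 x k count table (no continuity correction)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table_f = np.asarray(table, dtype=float)
        if np.any(table_f < 0) or np.any(table_f != np.round(table_f)):
            raise ValueError("chi_square requires non-negative integer counts")
        table = table_f.astype(int)
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("chi_square requires positive margins")
    res = stats.chi2_contingency(table, correction=False)
    return TestResult(marker="", method="chi_square",
                      statistic=float(res.statistic), p_raw=float(res.pvalue),
                      extra={"df": int(res.dof)})


def holm_adjust(p_values) -> np.ndarray:
    """Holm-Bonferroni step-down adjusted p-values, in input order.

    Sort ascending, multiply the i-th smallest by (m - i), enforce monotone
    nondecreasing, cap at 1. Implemented directly (rather than through a
    library call) so it is cheap enough for Monte-Carlo calibration loops.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    stepped = p[order] * np.arange(m, 0, -1)
    adj = np.minimum(np.maximum.accumulate(stepped), 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def fold_differences(panel: BiomarkerPanel, alpha: float = 0.05) -> list[FoldDifference]:
    """Per-marker case/control median fold with Holm-flagged significance.

    The Mann-Whitney family spans the full marker panel; ``significant``
    means Holm-adjusted p < ``alpha``. Fold = case median / control median
    on the native scale (equivalently 10**(difference of median log10)).
    """
    cases = panel.group_panel(1).markers
    controls = panel.group_panel(0).markers
    if len(cases) == 0 or len(controls) == 0:
        raise ValueError("both steatosis groups must be non-empty")
    rows = []
    for m in panel.marker_names:
        x = cases[m].dropna().to_numpy()
        y = controls[m].dropna().to_numpy()
        res = mann_whitney(x, y)
        # 10^(difference of median log10): the median ratio on the log-median
        # scale (interpolated medians of even-sized groups are geometric)
        fold = float(10.0 ** (np.median(np.log10(x)) - np.median(np.log10(y))))
        rows.append((m, fold, res.p_raw))
    p_adj = holm_adjust([r[2] for r in rows])
    return [
        FoldDifference(marker=m, fold=fold, log2_fold=float(np.log2(fold)),
                       p_raw=p, p_adjusted=float(a), significant=bool(a < alpha))
        for (m, fold, p), a in zip(rows, p_adj)
    ]


def univariate_table(panel: BiomarkerPanel, alpha: float = 0.05) -> pd.DataFrame:
    """Tidy per-marker summary: medians/IQRs per group, U, p, Holm p, folds."""
    cases = panel.group_panel(1).markers
    controls = panel.group_panel(0).markers
    records = []
    for m in panel.marker_names:
        x = cases[m].dropna().to_numpy()
        y = controls[m].dropna().to_numpy()
        res = mann_whitney(x, y)
        med_x, q1x, q3x = _median_iqr(x)
        med_y, q1y, q3y = _median_iqr(y)
        records.append({
            "marker": m, "method": "mann_whitney", "statistic": res.statistic,
            "p_raw": res.p_raw, "median_case": med_x, "iqr_low_case": q1x,
            "iqr_high_case": q3x, "median_control": med_y, "iqr_low_control": q1y,
            "iqr_high_control": q3y,
            "fold": 10.0 ** (np.median(np.log10(x)) - np.median(np.log10(y))),
        })
    df = pd.DataFrame.from_records(records)
    df["p_adjusted"] = holm_adjust(df["p_raw"].to_numpy())
    df["significant"] = df["p_adjusted"] < alpha
    return df
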
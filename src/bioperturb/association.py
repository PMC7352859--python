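"""Association chain: univariate screening, multivariable logistic
regression with odds ratios, and ROC analysis with an optimal cutoff.

Variables passing a lenient univariate screen (p < 0.2 by default) enter a
multivariable logistic model, always adjusted for sex, age, BMI-for-age
z-score and waist circumference; continuous markers enter on the log10
scale so coefficients are per 1-log concentration changes. Single-marker
performance is summarized by the empirical ROC curve, trapezoidal AUC with
a DeLong analytic 95% CI, and the Youden-optimal cutoff in native units.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .panel import BiomarkerPanel
from .univariate import chi_square, mann_whitney

logger = logging.getLogger(__name__)

FORCED_COVARIATES = ("sex", "age", "bmi_z", "waist")


@dataclass
class LogisticModel:
    terms: pd.DataFrame        # name, coef, se, odds_ratio, ci_low, ci_high, p
    log_likelihood: float
    n: int
    converged: bool
    separation: bool
    adjustment_set: tuple


@dataclass
class ROCResult:
    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    auc_ci: tuple[float, float]
    youden_cutoff: float
    sens_at_cutoff: float
    spec_at_cutoff: float
    degenerate: bool = False


def univariate_screen(panel: BiomarkerPanel, alpha_entry: float = 0.2,
                      forced=FORCED_COVARIATES) -> list[str]:
    """Variables with univariate p < ``alpha_entry`` against steatosis.

    Continuous variables are screened with the Mann-Whitney test, the
    binary sex variable with Pearson chi-square. Forced adjustment
    covariates are always retained regardless of their p.
    """
    y = panel.steatosis.to_numpy()
    if len(set(y)) < 2:
        raise ValueError("outcome must have both classes")
    selected = [c for c in forced if c in panel.data.columns]
    candidates = list(panel.marker_names) + [
        c for c in ("age", "bmi_z", "waist") if c in panel.data.columns]
    for name in candidates:
        vals = panel.data[name]
        x1 = vals[y == 1].dropna().to_numpy()
        x0 = vals[y == 0].dropna().to_numpy()
        p = mann_whitney(x1, x0).p_raw
        if (alpha_entry >= 1.0 or p < alpha_entry) and name not in selected:
            selected.append(name)
    if "sex" in panel.data.columns:
        tab = pd.crosstab(panel.data["sex"], panel.steatosis).to_numpy()
        if tab.shape == (2, 2) and (tab.sum(axis=0) > 0).all() \
                and (tab.sum(axis=1) > 0).all():
            p_sex = chi_square(tab).p_raw
            if p_sex < alpha_entry and "sex" not in selected:
                selected.append("sex")
    return selected


def fit_logistic(design: pd.DataFrame, outcome,
                 add_intercept: bool = True) -> LogisticModel:
    """Maximum-likelihood logistic fit (IRLS) with Wald odds-ratio CIs.

    Raises on singular designs (naming the collinear terms); detects
    complete/quasi-separation (diverging coefficients or non-convergence)
    and flags it rather than reporting silently absurd odds ratios.
    """
    design = pd.DataFrame(design)
    y = np.asarray(outcome, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    X = design.to_numpy(dtype=float)
    if np.any(np.all(X == 0, axis=0)):
        zero = [c for c, z in zip(design.columns, np.all(X == 0, axis=0)) if z]
        raise ValueError(f"constant-zero design columns: {zero}")
    names = list(design.columns)
    if add_intercept:
        X = np.column_stack([np.ones(len(y)), X])
        names = ["intercept"] + names
    if len(y) <= X.shape[1]:
        raise ValueError("more terms than samples")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        _, r = np.linalg.qr(X)
        diag = np.abs(np.diag(r))
        bad = [names[i] for i in np.nonzero(diag < 1e-10 * diag.max())[0]]
        raise ValueError(f"singular design; collinear terms: {bad}")

    import warnings

    separation = False
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        except Exception:  # statsmodels PerfectSeparationError and kin
            separation = True
            fit = sm.Logit(y, X).fit(disp=0, maxiter=50, method="bfgs")
    converged = bool(fit.mle_retvals.get("converged", True)) \
        if isinstance(fit.mle_retvals, dict) else True
    coefs = np.asarray(fit.params, dtype=float)
    ses = np.asarray(fit.bse, dtype=float)
    # separation: likelihood driven to its supremum (perfect fit) or Wald
    # SEs exploding; raw coefficient size alone is not evidence, since a
    # slope per 1-log concentration change is legitimately large for
    # low-variance markers
    if (not converged or fit.llf > -1e-6
            or not np.all(np.isfinite(ses)) or np.any(ses > 1e3)):
        separation = True
    if separation:
        logger.warning("possible separation: coefficients may be unbounded "
                       "(infinite odds ratios); interpret with caution")
    terms = pd.DataFrame({
        "term": names,
        "coef": coefs,
        "se": ses,
        "odds_ratio": np.exp(coefs),
        "ci_low": np.exp(coefs - 1.96 * ses),
        "ci_high": np.exp(coefs + 1.96 * ses),
        "p": np.asarray(fit.pvalues, dtype=float),
    })
    return LogisticModel(terms=terms, log_likelihood=float(fit.llf),
                         n=len(y), converged=converged, separation=separation,
                         adjustment_set=tuple(
                             c for c in FORCED_COVARIATES if c in design.columns))


def association_model(panel: BiomarkerPanel, alpha_entry: float = 0.2,
                      log_markers: bool = True) -> LogisticModel:
    """Screen then fit the multivariable steatosis model on complete rows."""
    complete = panel.complete_rows()
    selected = univariate_screen(complete, alpha_entry=alpha_entry)
    design = pd.DataFrame(index=complete.data.index)
    for name in selected:
        vals = complete.data[name].astype(float)
        if log_markers and name in complete.marker_names:
            design[f"log10_{name}"] = np.log10(vals)
        else:
            design[name] = vals
    return fit_logistic(design, complete.steatosis.to_numpy())


def adjusted_marker_model(panel: BiomarkerPanel, marker: str,
                          log_marker: bool = True) -> LogisticModel:
    """Logistic model of steatosis on one marker, adjusted for sex, age,
    BMI-z and waist; the marker enters as log10 so its coefficient is the
    log-odds per 1-log concentration change."""
    complete = panel.complete_rows()
    design = pd.DataFrame(index=complete.data.index)
    vals = complete.data[marker].astype(float)
    design[f"log10_{marker}" if log_marker else marker] = (
        np.log10(vals) if log_marker else vals)
    for c in FORCED_COVARIATES:
        if c in complete.data.columns:
            design[c] = complete.data[c].astype(float)
    return fit_logistic(design, complete.steatosis.to_numpy())


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

def _delong_ci(scores: np.ndarray, labels: np.ndarray,
               auc: float) -> tuple[float, float]:
    """DeLong analytic 95% CI for the AUC (mid-rank placements handle ties)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # placement values via mid-ranks of the pooled sample
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    v10 = (all_ranks[:m] - pos_ranks) / n          # P(score_neg < pos_i)
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m    # P(pos > neg_j)
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s10 / m + s01 / n)
    lo, hi = auc - 1.96 * se, auc + 1.96 * se
    return (float(max(lo, 0.0)), float(min(hi, 1.0)))


def roc_curve(scores, labels) -> ROCResult:
    """Empirical ROC over all distinct score thresholds.

    AUC by the trapezoid rule (equal to the Mann-Whitney U identity
    U/(n1*n0) with mid-rank tie handling); 95% CI by DeLong. The Youden
    cutoff maximizes sensitivity + specificity - 1, ties broken toward
    higher specificity; a case is called positive when score >= cutoff.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = set(np.unique(labels))
    if classes - {0, 1} or len(classes) < 2:
        raise ValueError("labels must be binary with both classes present")
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())

    degenerate = np.all(scores == scores[0])
    # threshold sweep: descending distinct scores; predict positive if >= t
    thresholds = np.unique(scores)[::-1]
    sens = np.empty(len(thresholds) + 1)
    spec = np.empty(len(thresholds) + 1)
    for i, t in enumerate(thresholds):
        pred = scores >= t
        sens[i] = (pred & (labels == 1)).sum() / n1
        spec[i] = (~pred & (labels == 0)).sum() / n0
    sens[-1], spec[-1] = 1.0, 0.0  # threshold below the minimum
    # prepend the all-negative operating point
    sens = np.concatenate([[0.0], sens])
    spec = np.concatenate([[1.0], spec])
    order = np.argsort(1.0 - spec, kind="stable")
    fpr = (1.0 - spec)[order]
    tpr = sens[order]
    auc = float(np.trapezoid(tpr, fpr))
    if degenerate:
        auc = 0.5
        ci = (0.5, 0.5)
    else:
        ci = _delong_ci(scores, labels, auc)
    j = sens[1:-1] + spec[1:-1] - 1.0
    if len(j):
        best = np.flatnonzero(j == j.max())
        # among Youden ties prefer the higher-specificity operating point
        best_i = best[np.argmax(spec[1:-1][best])]
        cutoff = float(thresholds[best_i])
        s_at, sp_at = float(sens[1:-1][best_i]), float(spec[1:-1][best_i])
    else:  # pragma: no cover - len(thresholds) >= 1 always
        cutoff, s_at, sp_at = float("nan"), float("nan"), float("nan")
    return ROCResult(thresholds=thresholds, sensitivity=sens[1:-1],
                     specificity=spec[1:-1], auc=auc, auc_ci=ci,
                     youden_cutoff=cutoff, sens_at_cutoff=s_at,
                     spec_at_cutoff=sp_at, degenerate=bool(degenerate))


def marker_roc(panel: BiomarkerPanel, marker: str) -> ROCResult:
    """ROC of one marker's native-scale concentration against steatosis."""
    sub = panel.data[[marker, "steatosis"]].dropna()
    return roc_curve(sub[marker].to_numpy(), sub["steatosis"].to_numpy())
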
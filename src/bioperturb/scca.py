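"""Sparse canonical-correlation discriminant.

Finds a sparse weight vector u over the markers and a weight vector v over
centered group-indicator columns maximizing u' X' Y v subject to
||u||_2 <= 1, ||v||_2 <= 1 and L1 budgets ||u||_1 <= penalty_u,
||v||_1 <= penalty_v — the penalized rank-1 matrix-decomposition
formulation of sparse CCA, solved by alternating soft-thresholded power
iterations (the soft threshold reaching the L1 budget is found by
bisection). The canonical score X u is the discriminant; the magnitude of
each marker's canonical coefficient ranks its contribution to group
separation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


@dataclass
class SCCAModel:
    u: np.ndarray                # per-marker canonical weights (sparse)
    v: np.ndarray                # per-indicator-column weights
    penalty_u: float
    penalty_v: float
    objective: float             # u' X'Y v at convergence
    canonical_correlation: float  # Pearson corr of X u and Y v
    scores: np.ndarray           # X u, oriented so cases score higher
    iterations: int
    converged: bool
    marker_names: list[str] = field(default_factory=list)
    degenerate: bool = False


def encode_groups(labels) -> np.ndarray:
    """Two centered indicator columns (control, case) for a binary outcome."""
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    Y = np.column_stack([(labels == 0).astype(float), (labels == 1).astype(float)])
    return Y - Y.mean(axis=0)


def _project(c: np.ndarray, budget: float, tol: float = 1e-10) -> np.ndarray:
    """argmax_u c'u over the intersection of the L2 unit ball and the L1 ball.

    Solution is soft-threshold then L2-normalize; the threshold delta >= 0 is
    the smallest making ||u(delta)||_1 <= budget, found by bisection.
    """
    norm = np.linalg.norm(c)
    if norm == 0:
        return np.zeros_like(c)
    u = c / norm
    if np.abs(u).sum() <= budget + tol:
        return u

    def l1_after(delta: float) -> float:
        s = np.sign(c) * np.maximum(np.abs(c) - delta, 0.0)
        n = np.linalg.norm(s)
        return np.abs(s).sum() / n if n > 0 else 0.0

    lo, hi = 0.0, float(np.abs(c).max())
    for _ in range(200):
        mid = (lo + hi) / 2.0
        if l1_after(mid) > budget:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol * max(1.0, hi):
            break
    s = np.sign(c) * np.maximum(np.abs(c) - hi, 0.0)
    n = np.linalg.norm(s)
    return s / n if n > 0 else np.zeros_like(c)


def _check_standardized(X: np.ndarray, tol: float = 1e-6) -> None:
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    nontrivial = sd > 0
    if np.abs(mu).max() > tol or (
            nontrivial.any() and np.abs(sd[nontrivial] - 1.0).max() > 1e-3):
        raise ValueError("X must be column-standardized (mean 0, sample SD 1)")


def fit_scca(X, Y, penalty_u: float | None = None, penalty_v: float | None = None,
             max_iter: int = 500, tol: float = 1e-8,
             marker_names=None) -> SCCAModel:
    """Fit the rank-1 sparse CCA of standardized markers X against group codes Y.

    Defaults: penalty_u = 1 + 0.5 (sqrt(p) - 1) (moderate sparsity),
    penalty_v = sqrt(q) (no sparsity on the outcome side). Initialization is
    the leading singular vector of X'Y, so the fit is deterministic.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with equal sample counts")
    p, q = X.shape[1], Y.shape[1]
    if penalty_u is None:
        penalty_u = 1.0 + 0.5 * (np.sqrt(p) - 1.0)
    if penalty_v is None:
        penalty_v = float(np.sqrt(q))
    if penalty_u < 1.0 or penalty_v < 1.0:
        raise ValueError("penalties must be >= 1 (L1 ball inside the L2 ball "
                         "is infeasible otherwise)")
    _check_standardized(X)
    if marker_names is None:
        marker_names = [f"m{i}" for i in range(p)]

    Z = X.T @ Y
    if not np.any(Z):
        logger.warning("X'Y is identically zero; degenerate sparse CCA fit")
        return SCCAModel(u=np.zeros(p), v=np.zeros(q), penalty_u=penalty_u,
                         penalty_v=penalty_v, objective=0.0,
                         canonical_correlation=0.0, scores=np.zeros(X.shape[0]),
                         iterations=0, converged=True,
                         marker_names=list(marker_names), degenerate=True)

    # deterministic init: leading singular pair of Z
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = _project(vt[0], penalty_v)
    u = np.zeros(p)
    converged = False
    iterations = 0
    for iterations in range(1, max_iter + 1):
        u_new = _project(Z @ v, penalty_u)
        v_new = _project(Z.T @ u_new, penalty_v)
        if np.max(np.abs(u_new - u)) < tol and np.max(np.abs(v_new - v)) < tol:
            u, v = u_new, v_new
            converged = True
            break
        u, v = u_new, v_new

    objective = float(u @ Z @ v)
    scores = X @ u
    yv = Y @ v
    if np.std(scores) > 0 and np.std(yv) > 0:
        ccor = float(np.corrcoef(scores, yv)[0, 1])
    else:
        ccor = 0.0
    # orient so the case column (assumed last indicator) scores higher
    case_dir = Y[:, -1]
    if np.std(scores) > 0 and np.corrcoef(scores, case_dir)[0, 1] < 0:
        u, v, scores = -u, -v, -scores
    return SCCAModel(u=u, v=v, penalty_u=float(penalty_u),
                     penalty_v=float(penalty_v), objective=abs(objective),
                     canonical_correlation=ccor, scores=scores,
                     iterations=iterations, converged=converged,
                     marker_names=list(marker_names))


def canonical_coefficients(model: SCCAModel) -> pd.DataFrame:
    """Markers ranked by |canonical weight|; zero-weight markers flagged excluded."""
    df = pd.DataFrame({
        "marker": model.marker_names,
        "weight": model.u,
        "abs_weight": np.abs(model.u),
    })
    df["excluded"] = df["weight"] == 0.0
    return (df.sort_values("abs_weight", ascending=False, kind="stable")
              .reset_index(drop=True))


def scca_discriminant_roc(X, labels, penalty_u=None, penalty_v=None,
                          mode: str = "resubstitution"):
    """ROC of the canonical score as a case/control classifier.

    ``resubstitution`` scores the training data with the single fitted model
    (optimistic; a warning is logged). ``loo_cv`` refits the sparse CCA with
    each sample left out — the held-out sample is standardized with the
    training fold's means/SDs before scoring.
    """
    from .association import roc_curve

    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    if len(set(np.unique(labels))) < 2:
        raise ValueError("both classes required")
    if mode == "resubstitution":
        logger.warning("resubstitution ROC is optimistic; consider mode='loo_cv'")
        model = fit_scca(X, encode_groups(labels), penalty_u, penalty_v)
        return roc_curve(model.scores, labels), model
    if mode != "loo_cv":
        raise ValueError("mode must be 'resubstitution' or 'loo_cv'")
    n = X.shape[0]
    scores = np.empty(n)
    for i in range(n):
        keep = np.ones(n, dtype=bool)
        keep[i] = False
        Xt = X[keep]
        mu, sd = Xt.mean(axis=0), Xt.std(axis=0, ddof=1)
        sd = np.where(sd > 0, sd, 1.0)
        model = fit_scca((Xt - mu) / sd, encode_groups(labels[keep]),
                         penalty_u, penalty_v)
        scores[i] = ((X[i] - mu) / sd) @ model.u
    full = fit_scca((X - X.mean(axis=0)) / X.std(axis=0, ddof=1),
                    encode_groups(labels), penalty_u, penalty_v)
    return roc_curve(scores, labels), full


def vector_projection(X, Y, penalty_u=None, penalty_v=None,
                      marker_names=None):
    """Sample coordinates on canonical variates 1-2 plus marker direction vectors.

    The second pair is fit on the rank-1-deflated cross-product
    Z - (u'Zv) u v'; when Y is effectively rank 1 (two-group indicators) the
    deflated matrix is ~0 and the second pair is flagged degenerate. Marker
    vectors are the Pearson correlations of each marker with the two
    variates.
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    first = fit_scca(X, Y, penalty_u, penalty_v, marker_names=marker_names)
    Z = X.T @ Y
    d = first.u @ Z @ first.v
    Z2 = Z - d * np.outer(first.u, first.v)
    # a second pair only exists when the cross-product has a second dimension
    svals = np.linalg.svd(Z, compute_uv=False)
    degenerate2 = len(svals) < 2 or svals[1] < 1e-8 * max(svals[0], 1.0)
    if degenerate2:
        scores2 = np.zeros(X.shape[0])
    else:
        second = _fit_on_crossproduct(X, Z2, first.penalty_u, first.penalty_v)
        scores2 = X @ second
    coords = np.column_stack([first.scores, scores2])
    vectors = np.zeros((X.shape[1], 2))
    for j in range(X.shape[1]):
        for k in range(2):
            if np.std(coords[:, k]) > 0 and np.std(X[:, j]) > 0:
                vectors[j, k] = np.corrcoef(X[:, j], coords[:, k])[0, 1]
    names = first.marker_names
    return (pd.DataFrame(coords, columns=["variate_1", "variate_2"]),
            pd.DataFrame(vectors, index=names, columns=["variate_1", "variate_2"]),
            first, degenerate2)


def _fit_on_crossproduct(X, Z, penalty_u, penalty_v,
                         max_iter: int = 500, tol: float = 1e-8) -> np.ndarray:
    _, _, vt = np.linalg.svd(Z, full_matrices=False)
    v = _project(vt[0], penalty_v)
    u = np.zeros(Z.shape[0])
    for _ in range(max_iter):
        u_new = _project(Z @ v, penalty_u)
        v_new = _project(Z.T @ u_new, penalty_v)
        if np.max(np.abs(u_new - u)) < tol and np.max(np.abs(v_new - v)) < tol:
            return u_new
        u, v = u_new, v_new
    return u
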
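"""Ward hierarchical clustering with bootstrap cluster support.

Clustering of log10 + z-scored marker data uses Ward's minimum-variance
linkage on Euclidean distances. Bootstrap support of an internal node is
the proportion of feature-resampled replicate trees that contain the
identical leaf cluster (when clustering markers, features are the
participants, so support reflects resampling people). 100 replicates by
default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .panel import BiomarkerPanel


@dataclass
class Dendrogram:
    """Ward dendrogram over ``labels`` (items = rows of the clustered matrix).

    ``linkage_matrix`` is the (n-1) x 4 scipy linkage encoding; merge
    heights are nondecreasing for Ward on Euclidean distances.
    ``bootstrap_support`` (if computed) maps each internal node, identified
    by its frozenset of leaf indices, to the replicate proportion containing
    that exact cluster.
    """

    linkage_matrix: np.ndarray
    labels: list[str]
    bootstrap_support: dict[frozenset, float] | None = None

    @property
    def leaf_order(self) -> list[int]:
        return list(hierarchy.leaves_list(self.linkage_matrix))

    @property
    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]

    def clusters(self) -> list[frozenset]:
        """Leaf-index sets of all internal nodes, in merge order."""
        return _cluster_sets(self.linkage_matrix)

    def support_table(self) -> pd.DataFrame:
        """Internal nodes with member labels, height and support."""
        rows = []
        for k, members in enumerate(self.clusters()):
            rows.append({
                "node": k,
                "members": ";".join(self.labels[i] for i in sorted(members)),
                "height": float(self.linkage_matrix[k, 2]),
                "support": (None if self.bootstrap_support is None
                            else self.bootstrap_support.get(members)),
            })
        return pd.DataFrame(rows)

    def to_newick(self) -> str:
        """Newick text with branch lengths from merge heights."""
        n = len(self.labels)
        heights = {i: 0.0 for i in range(n)}
        trees = {i: _quote(self.labels[i]) for i in range(n)}
        for k, (a, b, h, _) in enumerate(self.linkage_matrix):
            a, b = int(a), int(b)
            node = n + k
            la = max(h - heights[a], 0.0)
            lb = max(h - heights[b], 0.0)
            trees[node] = f"({trees[a]}:{la:g},{trees[b]}:{lb:g})"
            heights[node] = h
        return trees[n + len(self.linkage_matrix) - 1] + ";"


def _quote(label: str) -> str:
    return "'" + label.replace("'", "''") + "'" if any(
        c in label for c in " ():,;[]'") else label


def _cluster_sets(Z: np.ndarray) -> list[frozenset]:
    n = Z.shape[0] + 1
    members: dict[int, frozenset] = {i: frozenset([i]) for i in range(n)}
    out = []
    for k, (a, b, *_rest) in enumerate(Z):
        merged = members[int(a)] | members[int(b)]
        members[n + k] = merged
        out.append(merged)
    return out


def ward_cluster(matrix, labels=None) -> Dendrogram:
    """Ward linkage of an items x features matrix.

    Deterministic given input order; ties resolved by scipy's fixed
    nearest-neighbor chain order (lowest index first among equals). Missing
    values are rejected — apply listwise deletion upstream.
    """
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 items")
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; listwise-delete upstream")
    if labels is None:
        labels = [str(i) for i in range(X.shape[0])]
    Z = hierarchy.linkage(X, method="ward")
    return Dendrogram(linkage_matrix=Z, labels=list(labels))


def bootstrap_support(matrix, labels=None, n_boot: int = 100,
                      seed: int | None = None) -> Dendrogram:
    """Ward dendrogram with feature-bootstrap cluster support.

    Features (columns) are resampled with replacement ``n_boot`` times; the
    support of each internal node of the point-estimate tree is the
    proportion of replicate trees containing the identical leaf set.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    X = np.asarray(matrix, dtype=float)
    if X.shape[1] < 3:
        raise ValueError("bootstrap support needs >= 3 features")
    dendro = ward_cluster(X, labels)
    base_sets = dendro.clusters()
    counts = {s: 0 for s in base_sets}
    rng = np.random.default_rng(seed)
    for _ in range(n_boot):
        cols = rng.integers(0, X.shape[1], size=X.shape[1])
        rep_sets = set(_cluster_sets(hierarchy.linkage(X[:, cols], method="ward")))
        for s in counts:
            if s in rep_sets:
                counts[s] += 1
    dendro.bootstrap_support = {s: c / n_boot for s, c in counts.items()}
    return dendro


def grade_profile_matrix(panel: BiomarkerPanel, stat: str = "median",
                         include_covariates: bool = False) -> pd.DataFrame:
    """Markers x 3 matrix of grade-group profiles, row z-scored.

    Per marker: the per-grade-group median (default; ``stat="mean"``
    switches) of log10 values, then z-scored across the three group values
    (sample SD). Rows with identical group values become zeros. The result
    feeds Ward clustering of severity profiles.
    """
    if stat not in ("median", "mean"):
        raise ValueError("stat must be 'median' or 'mean'")
    cols = list(panel.marker_names)
    if include_covariates:
        cols = cols + [c for c in ("bmi_z", "waist") if c in panel.data.columns]
    grades = sorted(panel.grade.unique())
    if set(grades) != {0, 1, 2}:
        raise ValueError("all three grade groups (0, 1, 2) must be non-empty")
    profiles = {}
    for m in cols:
        vals = panel.data[m] if m in ("bmi_z",) else np.log10(panel.data[m])
        agg = np.array([
            getattr(np, stat)(vals[panel.grade == g].dropna()) for g in grades
        ], dtype=float)
        sd = agg.std(ddof=1)
        profiles[m] = np.zeros(3) if sd == 0 else (agg - agg.mean()) / sd
    return pd.DataFrame(profiles, index=[f"grade_{g}" for g in grades]).T
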
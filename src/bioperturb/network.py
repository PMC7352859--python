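"""Per-group Spearman correlation networks.

Markers are nodes; an undirected signed edge joins two markers when their
Spearman correlation has unadjusted p < alpha (0.05 by default — the
inclusion rule is deliberately unadjusted, with optional Holm/BH control
behind a flag). Participant-bootstrap support of each edge is reported
alongside, never used for edge selection.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from .panel import BiomarkerPanel
from .univariate import holm_adjust


@dataclass
class Edge:
    a: str
    b: str
    rho: float
    p_raw: float
    sign: int                      # +1 / -1
    boot_support: float | None = None


@dataclass
class CorrelationNetwork:
    group: str
    nodes: list[str]
    edges: list[Edge] = field(default_factory=list)

    @property
    def degrees(self) -> dict[str, int]:
        d = {n: 0 for n in self.nodes}
        for e in self.edges:
            d[e.a] += 1
            d[e.b] += 1
        return d

    @property
    def n_positive(self) -> int:
        return sum(1 for e in self.edges if e.sign > 0)

    @property
    def n_negative(self) -> int:
        return sum(1 for e in self.edges if e.sign < 0)

    def edge_set(self) -> set[tuple[str, str, int]]:
        return {(e.a, e.b, e.sign) for e in self.edges}

    def to_graph(self) -> nx.Graph:
        g = nx.Graph(group=self.group)
        g.add_nodes_from(self.nodes)
        for e in self.edges:
            g.add_edge(e.a, e.b, rho=e.rho, p=e.p_raw, sign=e.sign,
                       support=float("nan") if e.boot_support is None
                       else e.boot_support)
        return g

    def edge_table(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "marker_a": e.a, "marker_b": e.b, "rho": e.rho, "p": e.p_raw,
            "sign": "+" if e.sign > 0 else "-", "support": e.boot_support,
        } for e in self.edges])


# ---------------------------------------------------------------------------
# Spearman correlation with exact small-n p
# ---------------------------------------------------------------------------

def _spearman_t_p(rho: float, n: int) -> float:
    """Two-sided p from the t approximation."""
    if n < 3 or abs(rho) >= 1.0:
        return 0.0 if abs(rho) >= 1.0 and n > 3 else 1.0
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return 2.0 * stats.t.sf(abs(t), n - 2)


def _spearman_exact_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided permutation p for tie-free pairs with n <= 7."""
    n = len(x)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    obs = abs(np.corrcoef(rx, ry)[0, 1])
    count = 0
    total = 0
    for perm in itertools.permutations(range(n)):
        r = np.corrcoef(rx, ry[list(perm)])[0, 1]
        if abs(r) >= obs - 1e-12:
            count += 1
        total += 1
    return count / total


def spearman_pair(x, y, exact_max_n: int = 7) -> tuple[float, float]:
    """Spearman rho (mid-ranks) and two-sided p for one marker pair.

    Exact permutation enumeration for tie-free pairs with n <= ``exact_max_n``,
    t approximation otherwise. Pairs with fewer than 4 complete observations
    are unavailable (returns (nan, nan)).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    n = len(x)
    if n < 4:
        return (float("nan"), float("nan"))
    if np.all(x == x[0]) or np.all(y == y[0]):
        return (float("nan"), float("nan"))
    rho = float(stats.spearmanr(x, y).statistic)
    ties = (len(np.unique(x)) < n) or (len(np.unique(y)) < n)
    if n <= exact_max_n and not ties:
        return rho, float(_spearman_exact_p(x, y))
    return rho, float(_spearman_t_p(rho, n))


def spearman_matrix(values) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise-complete Spearman rho and p matrices for a samples x markers table.

    With complete data and n large enough for the t approximation the whole
    matrix is computed vectorized from column mid-ranks; otherwise each pair
    falls back to :func:`spearman_pair` (exact enumeration for tiny tie-free
    pairs).
    """
    df = pd.DataFrame(values)
    cols = list(df.columns)
    n = len(df)
    complete = not df.isna().any().any()
    if complete and n > 7:
        ranks = df.rank().to_numpy()
        with np.errstate(invalid="ignore"):
            rho = np.corrcoef(ranks, rowvar=False)
        p = np.ones_like(rho)
        mask = ~np.eye(len(cols), dtype=bool)
        r = np.clip(rho[mask], -1.0, 1.0)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = r * np.sqrt((n - 2) / (1.0 - r * r))
        p[mask] = 2.0 * stats.t.sf(np.abs(t), n - 2)
        p[mask] = np.where(np.abs(r) >= 1.0, 0.0, p[mask])
        np.fill_diagonal(p, 0.0)
        return (pd.DataFrame(rho, index=cols, columns=cols),
                pd.DataFrame(p, index=cols, columns=cols))
    rho = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            r_ij, p_ij = spearman_pair(df[a], df[b])
            rho.loc[a, b] = rho.loc[b, a] = r_ij
            p.loc[a, b] = p.loc[b, a] = p_ij
    return rho, p


# ---------------------------------------------------------------------------
# network construction
# ---------------------------------------------------------------------------

def _analysis_frame(panel: BiomarkerPanel, include_covariates: bool) -> pd.DataFrame:
    df = panel.markers.copy()
    if include_covariates:
        for c in ("bmi_z", "waist"):
            if c in panel.data.columns:
                df[c] = panel.data[c].to_numpy()
    return df


def build_network(panel_subset: BiomarkerPanel, alpha: float = 0.05,
                  group: str = "", include_covariates: bool = False,
                  adjust: str = "none") -> CorrelationNetwork:
    """Correlation network of one clinical group.

    Edges where the (by default unadjusted) Spearman p < ``alpha``;
    ``adjust`` in {"none", "holm", "fdr_bh"} optionally applies multiplicity
    control to the edge family before thresholding.
    """
    if panel_subset.n_samples < 5:
        raise ValueError("network construction needs >= 5 samples")
    df = _analysis_frame(panel_subset, include_covariates)
    rho, p = spearman_matrix(df)
    cols = list(df.columns)
    pairs = [(a, b) for i, a in enumerate(cols) for b in cols[i + 1:]]
    p_vals = np.array([p.loc[a, b] for a, b in pairs])
    if adjust == "holm":
        p_use = holm_adjust(np.nan_to_num(p_vals, nan=1.0))
    elif adjust == "fdr_bh":
        from statsmodels.stats.multitest import multipletests
        p_use = multipletests(np.nan_to_num(p_vals, nan=1.0), method="fdr_bh")[1]
    elif adjust == "none":
        p_use = p_vals
    else:
        raise ValueError(f"unknown adjust {adjust!r}")
    edges = []
    for (a, b), p_raw, p_sel in zip(pairs, p_vals, p_use):
        r = rho.loc[a, b]
        if np.isnan(p_sel) or np.isnan(r) or r == 0:
            continue
        if p_sel < alpha:
            edges.append(Edge(a=a, b=b, rho=float(r), p_raw=float(p_raw),
                              sign=1 if r > 0 else -1))
    return CorrelationNetwork(group=group, nodes=cols, edges=edges)


def bootstrap_network(panel_subset: BiomarkerPanel, n_boot: int = 100,
                      alpha: float = 0.05, group: str = "",
                      include_covariates: bool = False,
                      seed: int | None = None) -> CorrelationNetwork:
    """Point-estimate network with participant-bootstrap edge support.

    Support of an edge = fraction of ``n_boot`` row-resampled replicates in
    which the edge passes the alpha rule with the same sign. Edges of the
    point-estimate network are retained regardless of support.
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    net = build_network(panel_subset, alpha=alpha, group=group,
                        include_covariates=include_covariates)
    rng = np.random.default_rng(seed)
    n = panel_subset.n_samples
    counts = {(e.a, e.b, e.sign): 0 for e in net.edges}
    for _ in range(n_boot):
        idx = rng.integers(0, n, size=n)
        rep = build_network(panel_subset.subset(idx), alpha=alpha, group=group,
                            include_covariates=include_covariates)
        rep_edges = rep.edge_set()
        for key in counts:
            if key in rep_edges:
                counts[key] += 1
    for e in net.edges:
        e.boot_support = counts[(e.a, e.b, e.sign)] / n_boot
    return net


def node_degree_table(networks: list[CorrelationNetwork]) -> pd.DataFrame:
    """Markers x groups table of node degrees.

    Also carries per-group totals of positive and negative edges as the
    last two rows (``_total_positive`` / ``_total_negative``).
    """
    if not networks:
        raise ValueError("need at least one network")
    nodes = networks[0].nodes
    for net in networks[1:]:
        if set(net.nodes) != set(nodes):
            raise ValueError("networks must share a node set")
    table = {net.group: [net.degrees[n] for n in nodes] for net in networks}
    df = pd.DataFrame(table, index=nodes)
    df.loc["_total_positive"] = [net.n_positive for net in networks]
    df.loc["_total_negative"] = [net.n_negative for net in networks]
    return df
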
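"""Protein–protein interaction network centrality ranking.

Builds a confidence-thresholded undirected interaction graph (STRING
-style edge lists, combined score > 0.7 by default), computes five node
centralities — degree, betweenness, closeness, stress, eccentricity —
plus PageRank, and ranks nodes by a weighted sum of min–max-normalized
centralities. The weight ordering puts degree and stress highest,
then betweenness, closeness and eccentricity in descending order;
eccentricity is inverted before normalization so that peripheral nodes
(large eccentricity) contribute least. Candidate drug targets are the
top-k ranked nodes whose measured fold change clears |FC| >= 1.5, taken
separately from the weighted ranking and from PageRank and reported as a
union with provenance flags.

Metrics on disconnected graphs are computed per connected component
(shortest-path sums never cross components), matching how desktop
network-analysis tools treat undirected networks.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "DEFAULT_WEIGHTS",
    "TargetRanking",
    "build_network",
    "read_edge_list",
    "compute_centralities",
    "stress_centrality",
    "weighted_rank",
    "pagerank",
    "select_targets",
]

log = logging.getLogger(__name__)

#: Default centrality weights; ordering (degree = stress > betweenness >
#: closeness > eccentricity) is fixed by design, the exact values are a
#: configuration parameter.
DEFAULT_WEIGHTS = {
    "degree": 0.28,
    "stress": 0.28,
    "betweenness": 0.20,
    "closeness": 0.14,
    "eccentricity": 0.10,
}

METRICS = list(DEFAULT_WEIGHTS)


@dataclass
class TargetRanking:
    """Weighted centrality ranking with optional target selection."""

    scores: pd.DataFrame  # per-node centralities, normalized values, score, rank
    weights: dict[str, float]
    pagerank: pd.Series | None = None
    selected: pd.DataFrame | None = field(default=None)
    fc_min: float | None = None
    top_k: int | None = None

    @property
    def order(self) -> list[str]:
        return list(self.scores.index)


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------


def build_network(
    edges,
    min_confidence: float = 0.7,
    nodes: list[str] | None = None,
) -> nx.Graph:
    """Confidence-filtered undirected simple graph.

    ``edges`` is an iterable of ``(a, b, confidence)`` (or a DataFrame
    whose first three columns are read that way). Edges at or below the
    threshold are dropped (strict ``> min_confidence``); duplicates
    collapse to the maximum confidence; self-loops are dropped with a
    warning. Nodes listed in ``nodes`` are kept even if isolated.
    """
    if isinstance(edges, pd.DataFrame):
        edges = edges.iloc[:, :3].itertuples(index=False)
    G = nx.Graph()
    if nodes:
        G.add_nodes_from(nodes)
    n_self = 0
    for a, b, conf in edges:
        conf = float(conf)
        if not 0.0 <= conf <= 1.0:
            raise ValueError(f"confidence {conf} outside [0, 1] for edge ({a}, {b})")
        if a == b:
            n_self += 1
            continue
        if conf <= min_confidence:
            continue
        if G.has_edge(a, b):
            G[a][b]["confidence"] = max(G[a][b]["confidence"], conf)
        else:
            G.add_edge(a, b, confidence=conf)
    if n_self:
        warnings.warn(f"dropped {n_self} self-loop edges")
    return G


def read_edge_list(path: str | Path) -> pd.DataFrame:
    """Read a STRING-dialect TSV edge list.

    Expects columns ``protein1``, ``protein2`` and ``combined_score``
    (or the first three columns in that order). Scores on the STRING
    0–1000 integer scale are auto-detected (any score > 1) and rescaled
    to [0, 1]; the detection is logged.
    """
    df = pd.read_csv(path, sep=r"\s+|\t|,", engine="python")
    cols = list(df.columns)
    want = ["protein1", "protein2", "combined_score"]
    if not set(want) <= set(cols):
        df = df.iloc[:, :3]
        df.columns = want
    df = df[want].copy()
    if (df["combined_score"] > 1).any():
        log.info("edge scores on 0–1000 scale detected; rescaling to [0, 1]")
        df["combined_score"] = df["combined_score"] / 1000.0
    return df


# ---------------------------------------------------------------------------
# centralities
# ---------------------------------------------------------------------------


def _bfs_counts(G: nx.Graph, nodes: list[str]):
    """All-pairs geodesic distances and shortest-path counts (BFS per source)."""
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    D = np.full((n, n), np.inf)
    C = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        D[si, si] = 0
        C[si, si] = 1
        frontier = [s]
        dist = 0
        while frontier:
            nxt = []
            for u in frontier:
                for w in G[u]:
                    wi = idx[w]
                    if np.isinf(D[si, wi]):
                        D[si, wi] = dist + 1
                        nxt.append(w)
                    if D[si, wi] == dist + 1:
                        C[si, wi] += C[si, idx[u]]
            frontier = nxt
            dist += 1
    return D, C


def stress_centrality(G: nx.Graph) -> dict[str, int]:
    """Raw counts of shortest paths through each node.

    ``stress(v) = Σ_{s<t, s≠v≠t} σ_st(v)`` where σ_st(v) is the number of
    s–t geodesics passing through v. Computed per connected component.
    """
    out: dict[str, int] = {v: 0 for v in G}
    for comp in nx.connected_components(G):
        nodes = sorted(comp)
        D, C = _bfs_counts(G, nodes)
        n = len(nodes)
        pair = np.triu(np.ones((n, n), dtype=bool), k=1)
        for vi, v in enumerate(nodes):
            # σ_st(v) = σ_sv · σ_vt when v lies on an s–t geodesic
            on_path = (D[:, vi][:, None] + D[vi, :][None, :]) == D
            counts = C[:, vi][:, None] * C[vi, :][None, :]
            mask = pair & on_path
            mask[vi, :] = False
            mask[:, vi] = False
            out[v] = int(round(counts[mask].sum()))
    return out


def compute_centralities(network: nx.Graph) -> pd.DataFrame:
    """Five per-node centralities, computed per connected component.

    degree: incident edge count. betweenness: fraction of s–t geodesics
    through the node, normalized by (n−1)(n−2)/2 within its component.
    closeness: (n_comp − 1) / Σ geodesic distances within the component.
    stress: raw geodesic count through the node. eccentricity: maximum
    geodesic distance within the component.
    """
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    rows = {}
    stress = stress_centrality(network)
    for comp in nx.connected_components(network):
        sub = network.subgraph(comp)
        betw = nx.betweenness_centrality(sub, normalized=True)
        close = nx.closeness_centrality(sub, wf_improved=False)
        ecc = nx.eccentricity(sub)
        for v in comp:
            rows[v] = {
                "degree": network.degree[v],
                "betweenness": betw[v],
                "closeness": close[v],
                "stress": stress[v],
                "eccentricity": ecc[v],
            }
    df = pd.DataFrame(rows).T.loc[sorted(network.nodes())]
    df.index.name = "node"
    return df[METRICS]


def pagerank(network: nx.Graph, damping: float = 0.85, tol: float = 1e-10) -> pd.Series:
    """PageRank of the undirected graph (each edge walked both ways)."""
    if network.number_of_nodes() == 0:
        raise ValueError("empty network")
    pr = nx.pagerank(network, alpha=damping, tol=tol, max_iter=1000)
    return pd.Series(pr).sort_index()


# ---------------------------------------------------------------------------
# ranking
# ---------------------------------------------------------------------------


def _minmax(col: pd.Series, invert: bool = False) -> pd.Series:
    lo, hi = float(col.min()), float(col.max())
    if hi == lo:
        return pd.Series(1.0, index=col.index)
    x = (col - lo) / (hi - lo)
    return 1.0 - x if invert else x


def weighted_rank(
    records: pd.DataFrame, weights: dict[str, float] | None = None
) -> TargetRanking:
    """Rank nodes by a weighted sum of normalized centralities.

    Each metric is min–max normalized to [0, 1] across nodes
    (eccentricity inverted first, so low eccentricity scores high); the
    weighted score is the weight-dot-normalized-metric sum. Ties are
    broken lexicographically by node id so the ordering is total. When a
    metric is constant across nodes (including single-node networks) its
    normalized value is 1 for everyone.
    """
    weights = dict(weights or DEFAULT_WEIGHTS)
    unknown = set(weights) - set(METRICS)
    if unknown:
        raise ValueError(f"unknown metrics in weights: {unknown}")
    if any(w < 0 for w in weights.values()) or not any(weights.values()):
        raise ValueError("weights must be nonnegative and not all zero")

    out = records.copy()
    score = pd.Series(0.0, index=out.index)
    for metric, w in weights.items():
        norm = _minmax(out[metric], invert=(metric == "eccentricity"))
        out[f"{metric}_norm"] = norm
        score = score + w * norm
    out["score"] = score
    # deterministic total order: descending score, ties lexicographic by node id
    out = out.iloc[np.lexsort((out.index.astype(str), -out["score"].to_numpy()))]
    out["rank"] = np.arange(1, len(out) + 1)
    return TargetRanking(scores=out, weights=weights)


def select_targets(
    ranking: TargetRanking,
    fold_changes: dict[str, float],
    fc_min: float = 1.5,
    top_k: int = 10,
    pagerank_scores: pd.Series | None = None,
) -> TargetRanking:
    """Top-k high-fold-change nodes from the weighted and PageRank orders.

    Nodes failing ``|log2 FC| >= log2(fc_min)`` are removed before the
    top-k cut; nodes without a fold-change entry are excluded with a
    warning. The returned selection is the union of both top-k lists
    with provenance flags (``in_weighted_top``, ``in_pagerank_top``).
    """
    if fc_min <= 0:
        raise ValueError("fc_min must be a positive ratio")
    nodes = ranking.order
    missing = [v for v in nodes if v not in fold_changes]
    if missing:
        warnings.warn(f"{len(missing)} nodes without fold-change entries excluded")
    cut = np.log2(fc_min)
    passing = [
        v
        for v in nodes
        if v in fold_changes and abs(np.log2(fold_changes[v])) >= cut
    ]
    weighted_top = passing[:top_k]

    pagerank_top: list[str] = []
    if pagerank_scores is not None:
        order = np.lexsort(
            (pagerank_scores.index.astype(str), -pagerank_scores.to_numpy())
        )
        pr_order = list(pagerank_scores.index[order])
        pr_pass = [
            v
            for v in pr_order
            if v in fold_changes and abs(np.log2(fold_changes[v])) >= cut
        ]
        pagerank_top = pr_pass[:top_k]

    union = list(dict.fromkeys(weighted_top + pagerank_top))
    sel = pd.DataFrame(
        {
            "node": union,
            "fc": [fold_changes[v] for v in union],
            "weighted_rank": [
                weighted_top.index(v) + 1 if v in weighted_top else None for v in union
            ],
            "pagerank_rank": [
                pagerank_top.index(v) + 1 if v in pagerank_top else None for v in union
            ],
            "in_weighted_top": [v in weighted_top for v in union],
            "in_pagerank_top": [v in pagerank_top for v in union],
        }
    ).set_index("node")
    return TargetRanking(
        scores=ranking.scores,
        weights=ranking.weights,
        pagerank=pagerank_scores,
        selected=sel,
        fc_min=fc_min,
        top_k=top_k,
    )
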
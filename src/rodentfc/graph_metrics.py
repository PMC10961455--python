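"""Density-thresholded graph construction and network parameters.

A connectivity matrix is symmetrised (element-wise mean of the two
directed entries) and reduced to the m = round(n k / 2) strongest
undirected edges, where the density parameter k is the target average
node degree (k = 6 keeps 240 of 3160 possible edges on 80 nodes, about
8%).  Global clustering and characteristic path length are normalised
against uniform G(n, m) random graphs with equal node and edge counts
(gamma, lambda), their ratio being the small-world index sigma = gamma /
lambda.  Local metrics (degree, strength, clustering, path length,
betweenness, hub score) are tabulated per node, and the laterality index
LI = (L - R) / (L + R) compares bilateral region pairs.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "ThresholdedGraph",
    "GlobalMetrics",
    "threshold_to_density",
    "global_metrics",
    "local_metrics",
    "laterality_index",
    "hub_table",
]

#: |LI| above which a bilateral pair counts as lateralised
LI_THRESHOLD = 0.3
#: percentile of the composite rank score above which a node is a hub
HUB_PERCENTILE = 90.0


@dataclasses.dataclass
class ThresholdedGraph:
    """Undirected graph at target density k with retained edge weights."""

    graph: nx.Graph
    k: int
    region_ids: np.ndarray

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()


@dataclasses.dataclass
class GlobalMetrics:
    gamma: float  # clustering normalised by the random-ensemble mean
    lam: float  # path length normalised likewise
    sigma: float  # small-world index gamma / lambda
    n_components: int
    raw_clustering: float
    raw_path_length: float


def _symmetrize(values: np.ndarray) -> np.ndarray:
    return 0.5 * (values + values.T)


def threshold_to_density(matrix: ConnectivityMatrix, k: int) -> ThresholdedGraph:
    """Keep the m = round(n k / 2) largest-weight undirected edges.

    The asymmetric matrix is symmetrised by the element-wise mean first.
    Ties at the cutoff are broken deterministically by (weight desc, row
    id, col id).  If fewer than m strictly positive weights exist, all
    positives are retained with a warning.
    """
    if k < 1:
        raise ValueError("density k must be >= 1")
    w = _symmetrize(matrix.values)
    ids = matrix.region_ids
    n = ids.size
    m = int(round(n * k / 2.0))
    iu, ju = np.triu_indices(n, 1)
    weights = w[iu, ju]
    order = np.lexsort((ju, iu, -weights))  # weight desc, then row, then col
    order = order[weights[order] > 0.0]
    if order.size < m:
        warnings.warn(
            f"only {order.size} positive weights available for {m} requested edges"
        )
    keep = order[:m]
    g = nx.Graph()
    g.add_nodes_from(int(r) for r in ids)
    for e in keep:
        g.add_edge(int(ids[iu[e]]), int(ids[ju[e]]), weight=float(weights[e]))
    return ThresholdedGraph(g, k, ids)


def _raw_global(g: nx.Graph) -> tuple[float, float]:
    """(average local clustering, characteristic path length over
    connected node pairs) of the binarised graph."""
    clustering = nx.average_clustering(g)
    total, pairs = 0, 0
    for comp in nx.connected_components(g):
        sub = g.subgraph(comp)
        if sub.number_of_nodes() < 2:
            continue
        for _, dists in nx.all_pairs_shortest_path_length(sub):
            total += sum(dists.values())
            pairs += len(dists) - 1  # drop self-distance
    path_length = total / pairs if pairs else float("nan")
    return clustering, path_length


def global_metrics(
    tg: ThresholdedGraph, n_random: int = 1000, seed: int | None = 0
) -> GlobalMetrics:
    """Normalised global parameters.

    Raw clustering and path length are divided by the means of the same
    metrics over ``n_random`` uniform G(n, m) random graphs with
    equivalent node and edge counts (seeded); sigma = gamma / lambda.
    """
    g = tg.graph
    if g.number_of_edges() == 0:
        raise ValueError("graph has no edges")
    raw_c, raw_l = _raw_global(g)
    rng = np.random.default_rng(seed)
    cs, ls = [], []
    n, m = g.number_of_nodes(), g.number_of_edges()
    for _ in range(n_random):
        rand = nx.gnm_random_graph(n, m, seed=int(rng.integers(2**31)))
        c, l = _raw_global(rand)
        cs.append(c)
        ls.append(l)
    mean_c, mean_l = float(np.mean(cs)), float(np.nanmean(ls))
    gamma = raw_c / mean_c if mean_c > 0 else float("nan")
    lam = raw_l / mean_l if mean_l > 0 else float("nan")
    sigma = gamma / lam if np.isfinite(gamma) and np.isfinite(lam) and lam != 0 else float("nan")
    return GlobalMetrics(
        gamma=gamma, lam=lam, sigma=sigma,
        n_components=nx.number_connected_components(g),
        raw_clustering=raw_c, raw_path_length=raw_l,
    )


def local_metrics(tg: ThresholdedGraph) -> pd.DataFrame:
    """Per-node table: degree, strength (sum of retained z-weights),
    clustering, path length (mean shortest-path distance to reachable
    nodes; NaN for isolated nodes), normalised betweenness, and the
    composite hub score.

    The hub score is the mean of a node's percentile ranks for degree,
    betweenness and inverse path length; nodes above its 90th percentile
    are flagged as hubs.
    """
    g = tg.graph
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")
    nodes = [int(r) for r in tg.region_ids]
    degree = dict(g.degree())
    strength = dict(g.degree(weight="weight"))
    clustering = nx.clustering(g)
    betweenness = nx.betweenness_centrality(g, normalized=True)
    path_len = {}
    for node in nodes:
        dists = nx.single_source_shortest_path_length(g, node)
        del dists[node]
        path_len[node] = float(np.mean(list(dists.values()))) if dists else np.nan

    df = pd.DataFrame(
        {
            "region_id": nodes,
            "degree": [degree[n] for n in nodes],
            "strength": [strength[n] for n in nodes],
            "clustering": [clustering[n] for n in nodes],
            "path_length": [path_len[n] for n in nodes],
            "betweenness": [betweenness[n] for n in nodes],
        }
    ).set_index("region_id", drop=False)

    def pct_rank(x: pd.Series) -> pd.Series:
        return x.rank(pct=True, na_option="keep") * 100.0

    with np.errstate(divide="ignore"):
        inv_pl = 1.0 / df["path_length"]
    composite = (
        pct_rank(df["degree"]) + pct_rank(df["betweenness"]) + pct_rank(inv_pl)
    ) / 3.0
    df["hub_score"] = composite
    df["is_hub"] = composite > np.nanpercentile(composite, HUB_PERCENTILE)
    return df


def laterality_index(
    values_left: np.ndarray, values_right: np.ndarray, threshold: float = LI_THRESHOLD
) -> pd.DataFrame:
    """LI = (L - R) / (L + R) per bilateral pair; 0 when both are 0.

    |LI| > ``threshold`` (default 0.3) flags hemispheric dominance.
    Inputs must be non-negative (degree/strength-like metrics).
    """
    left = np.asarray(values_left, dtype=float)
    right = np.asarray(values_right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left/right value arrays must align")
    if np.any(left < 0) or np.any(right < 0):
        raise ValueError("laterality inputs must be non-negative")
    total = left + right
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(total > 0, (left - right) / total, 0.0)
    return pd.DataFrame(
        {"left": left, "right": right, "li": li, "lateralized": np.abs(li) > threshold}
    )


def hub_table(tg: ThresholdedGraph) -> pd.DataFrame:
    """Convenience: rows of :func:`local_metrics` flagged as hubs."""
    df = local_metrics(tg)
    return df[df["is_hub"]]
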
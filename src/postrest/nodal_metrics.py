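"""Weighted nodal graph metrics and their area under the sparsity curve.

Conventions follow the Brain Connectivity Toolbox defaults: Onnela's weighted
clustering coefficient, shortest paths on lengths l = 1/w, global efficiency as
the mean inverse shortest-path length, local efficiency as the global
efficiency of the neighborhood subgraph, LEGE as local over global efficiency,
and Brandes betweenness on the same lengths, here normalized to [0, 1] by
(N-1)(N-2)/2. The participation coefficient needs a module partition, which is
obtained by seeded Louvain modularity maximization (best of several restarts,
canonical relabeling) since weighted metrics require a concrete community
assignment.
"""

from __future__ import annotations

import numpy as np

from .graph_build import SparseGraph

__all__ = [
    "degree_and_strength",
    "clustering_weighted",
    "efficiencies",
    "betweenness_weighted",
    "detect_communities",
    "participation",
    "metric_auc",
    "nodal_metrics_table",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "degree",
    "strength",
    "clustering",
    "local_efficiency",
    "lege",
    "betweenness",
    "participation",
]


def degree_and_strength(graph: SparseGraph) -> tuple[np.ndarray, np.ndarray]:
    """Edge count and summed edge weight incident to each node."""
    deg = np.bincount(graph.edges.ravel(), minlength=graph.n_nodes)
    strength = np.zeros(graph.n_nodes)
    np.add.at(strength, graph.edges[:, 0], graph.metric_weights)
    np.add.at(strength, graph.edges[:, 1], graph.metric_weights)
    return deg.astype(int), strength


def clustering_weighted(graph: SparseGraph) -> np.ndarray:
    """Onnela weighted clustering coefficient per node.

    C_i = (2 / (k_i (k_i - 1))) * sum over neighbor pairs (j, h) of
    (w_ij^ w_ih^ w_jh^)^(1/3) with weights normalized by the network maximum;
    0 for nodes with fewer than two neighbors.
    """
    import networkx as nx

    if np.any(graph.metric_weights <= 0):
        raise ValueError("clustering requires positive weights")
    vals = nx.clustering(graph.to_networkx(), weight="weight")
    return np.array([vals[k] for k in range(graph.n_nodes)])


def _inverse_distance_sum(adj: np.ndarray) -> np.ndarray:
    """Pairwise inverse shortest-path lengths on l = 1/w; 0 for unreachable."""
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import dijkstra

    with np.errstate(divide="ignore"):
        lengths = np.where(adj > 0, 1.0 / adj, 0.0)
    d = dijkstra(csr_matrix(lengths), directed=False)
    with np.errstate(divide="ignore"):
        inv = np.where(np.isfinite(d) & (d > 0), 1.0 / d, 0.0)
    return inv


def efficiencies(graph: SparseGraph) -> tuple[float, np.ndarray, np.ndarray]:
    """(global efficiency, local efficiency vector, LEGE vector).

    Global efficiency is the mean of 1/d_ij over ordered node pairs. Local
    efficiency of node i is the global efficiency of the subgraph induced on
    its neighbors (0 with fewer than 2 neighbors); LEGE divides it by the
    global efficiency.
    """
    n = graph.n_nodes
    adj = graph.adjacency()
    inv = _inverse_distance_sum(adj)
    e_glob = float(inv.sum() / (n * (n - 1))) if n > 1 else 0.0
    if e_glob <= 0:
        raise RuntimeError("global efficiency is zero on a connected graph")

    neighbors = [np.flatnonzero(adj[k] > 0) for k in range(n)]
    e_loc = np.zeros(n)
    for k in range(n):
        nb = neighbors[k]
        if nb.size < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        sub_inv = _inverse_distance_sum(sub)
        e_loc[k] = sub_inv.sum() / (nb.size * (nb.size - 1))
    return e_glob, e_loc, e_loc / e_glob


def betweenness_weighted(graph: SparseGraph) -> np.ndarray:
    """Shortest-path betweenness on lengths 1/w, normalized to [0, 1].

    All geodesics between a pair share the through-node credit; normalization
    divides by the (N-1)(N-2)/2 pairs that could route through a node.
    """
    import networkx as nx

    vals = nx.betweenness_centrality(
        graph.to_networkx(), weight="length", normalized=True
    )
    return np.array([vals[k] for k in range(graph.n_nodes)])


def detect_communities(graph: SparseGraph, seed: int = 0, restarts: int = 10) -> np.ndarray:
    """Louvain modularity partition, best of ``restarts`` seeded runs.

    Returns a module label per node. Labels are canonicalized (modules numbered
    by their smallest member) so equal partitions compare equal, and the best
    run is chosen by modularity with the run index as deterministic tie-break.
    """
    import networkx as nx

    G = graph.to_networkx()
    best: list[set] | None = None
    best_q = -np.inf
    for r in range(restarts):
        comms = nx.community.louvain_communities(G, weight="weight", seed=seed + r)
        q = nx.community.modularity(G, comms, weight="weight")
        if q > best_q + 1e-12:
            best_q, best = q, comms
    assert best is not None
    ordered = sorted((min(c), c) for c in best)
    labels = np.empty(graph.n_nodes, dtype=int)
    for new_label, (_, members) in enumerate(ordered):
        for node in members:
            labels[node] = new_label
    return labels


def participation(graph: SparseGraph, partition: np.ndarray) -> np.ndarray:
    """Participation coefficient P_i = 1 - sum_m (s_im / s_i)^2.

    s_im is node i's summed weight to module m. 0 when all of a node's weight
    stays within one module, approaching 1 for evenly spread connectors.
    """
    partition = np.asarray(partition, dtype=int)
    if partition.shape[0] != graph.n_nodes:
        raise ValueError("partition must label every node")
    n_mod = partition.max() + 1
    s_im = np.zeros((graph.n_nodes, n_mod))
    for (i, j), w in zip(graph.edges, graph.metric_weights):
        s_im[i, partition[j]] += w
        s_im[j, partition[i]] += w
    s = s_im.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        frac = np.where(s[:, None] > 0, s_im / s[:, None], 0.0)
    return 1.0 - (frac**2).sum(axis=1)


def metric_auc(sparsities: np.ndarray, values: np.ndarray) -> float | np.ndarray:
    """Trapezoidal area under a metric curve over the sparsity grid.

    ``values`` may be 1-D (one curve) or 2-D (curves in rows, grid on the last
    axis); sparsities are fractions, so a constant c over [0.12, 0.28] yields
    0.16 c.
    """
    sparsities = np.asarray(sparsities, dtype=float)
    values = np.asarray(values, dtype=float)
    if values.shape[-1] != sparsities.shape[0]:
        raise ValueError("one value per grid point required")
    if sparsities.shape[0] < 2:
        raise ValueError("AUC needs at least two grid points")
    return np.trapezoid(values, sparsities, axis=-1)


def nodal_metrics_table(
    ensemble: dict[tuple[str, str, float], SparseGraph],
    seed: int = 0,
    heavy: bool = True,
):
    """Long-format table of nodal metrics over a graph ensemble.

    One row per (subject, condition, sparsity, node); columns are the metric
    names plus the per-graph global efficiency. With ``heavy=False`` only
    degree and strength are computed (the cheap metrics used by the dynamic
    and screening analyses).
    """
    import pandas as pd

    rows = []
    for (sid, cond, dens) in sorted(ensemble):
        g = ensemble[(sid, cond, dens)]
        deg, stren = degree_and_strength(g)
        block = {
            "subject": sid,
            "condition": cond,
            "sparsity": dens,
            "node": np.arange(g.n_nodes),
            "degree": deg,
            "strength": stren,
        }
        if heavy:
            e_glob, e_loc, lege = efficiencies(g)
            part = participation(g, detect_communities(g, seed=seed))
            block.update(
                clustering=clustering_weighted(g),
                local_efficiency=e_loc,
                lege=lege,
                betweenness=betweenness_weighted(g),
                participation=part,
                global_efficiency=e_glob,
            )
        rows.append(pd.DataFrame(block))
    return pd.concat(rows, ignore_index=True)
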
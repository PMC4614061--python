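"""Connectedness-preserving graph sparsification over a sparsity grid.

A weighted undirected graph is thinned by recursively removing the weakest
edges while never disconnecting the graph: edges are examined in ascending
signed weight (ties broken by the lexicographic node pair) and an edge whose
removal would disconnect the graph is retained, the next weakest being removed
instead, until the target edge count ``m = round(density * N(N-1)/2)`` remains.

With a strict total order on edges this procedure is the classical
reverse-delete algorithm: the edges ever retained as bridges are exactly the
maximum-spanning-tree edges under that order, and the removable edges fall in
ascending order. The implementation exploits this equivalence — one Kruskal
pass marks the spanning-tree edges, then the weakest non-tree edges are dropped
until ``m`` remain — which is exact, deterministic and fast enough to sweep a
whole density grid from a single ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "SparseGraph",
    "sparsify_preserving_connectivity",
    "sparsify_grid",
    "build_graph_ensemble",
    "is_connected",
    "graph_density",
    "WEIGHT_FLOOR",
]

WEIGHT_FLOOR = 1e-6  # metric weight assigned to bridge-retained non-positive edges


@dataclass
class SparseGraph:
    """Weighted undirected graph at a target edge density, guaranteed connected.

    ``edges`` is an (m, 2) int array of node pairs (i < j), ``weights`` the
    original signed weights and ``metric_weights`` the strictly positive
    weights used by the nodal metrics (non-positive retained bridges floored at
    ``WEIGHT_FLOOR``).
    """

    n_nodes: int
    edges: np.ndarray
    weights: np.ndarray
    target_density: float
    bridge_forced: bool = False

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        self.weights = np.asarray(self.weights, dtype=float)
        if np.any(self.weights <= 0):
            n_bad = int(np.sum(self.weights <= 0))
            warnings.warn(
                f"{n_bad} retained edge(s) have non-positive weight; floored at "
                f"{WEIGHT_FLOOR} for metric computation",
                stacklevel=2,
            )
        self.metric_weights = np.where(self.weights > 0, self.weights, WEIGHT_FLOOR)

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def achieved_density(self) -> float:
        return graph_density(self)

    def adjacency(self, metric: bool = True) -> np.ndarray:
        """Dense symmetric adjacency (metric weights by default)."""
        w = self.metric_weights if metric else self.weights
        A = np.zeros((self.n_nodes, self.n_nodes))
        A[self.edges[:, 0], self.edges[:, 1]] = w
        A[self.edges[:, 1], self.edges[:, 0]] = w
        return A

    def to_networkx(self):
        import networkx as nx

        G = nx.Graph()
        G.add_nodes_from(range(self.n_nodes))
        for (i, j), w in zip(self.edges, self.metric_weights):
            G.add_edge(int(i), int(j), weight=float(w), length=1.0 / float(w))
        return G


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))
        self.rank = [0] * n

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        if self.rank[ra] < self.rank[rb]:
            ra, rb = rb, ra
        self.parent[rb] = ra
        if self.rank[ra] == self.rank[rb]:
            self.rank[ra] += 1
        return True


def _matrix_edges(matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Upper-triangle edges of a symmetric weight matrix.

    Entries that are exactly zero carry no edge (absent); a correlation of
    exactly 0.0 is a measure-zero event, so for connectivity matrices the
    start graph is in practice complete.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("weight matrix must be square")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("weight matrix must be symmetric")
    iu, ju = np.triu_indices(M.shape[0], k=1)
    w = M[iu, ju]
    present = w != 0.0
    return iu[present], ju[present], w[present]


def _ascending_order(i: np.ndarray, j: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Strict total order: ascending weight, ties by lexicographic (i, j)."""
    return np.lexsort((j, i, w))


def _spanning_tree_mask(
    n: int, i: np.ndarray, j: np.ndarray, order_asc: np.ndarray
) -> np.ndarray:
    """Mark the maximum-spanning-tree edges under the strict order.

    Kruskal over edges in descending order (exact reverse of the removal
    order) — with a strict total order the tree is unique and equals the set
    of edges the naive reverse-delete would retain as bridges.
    """
    mask = np.zeros(i.shape[0], dtype=bool)
    uf = _UnionFind(n)
    n_tree = 0
    for idx in order_asc[::-1]:
        if uf.union(int(i[idx]), int(j[idx])):
            mask[idx] = True
            n_tree += 1
            if n_tree == n - 1:
                break
    if n_tree < n - 1:
        raise ValueError("input graph is disconnected; cannot sparsify to a connected graph")
    return mask


def sparsify_preserving_connectivity(
    matrix: np.ndarray, density: float
) -> SparseGraph:
    """Sparsify a weighted graph to ``density`` without disconnecting it."""
    graphs = sparsify_grid(matrix, [density])
    return graphs[density]


def sparsify_grid(
    matrix: np.ndarray, grid: list[float] | tuple[float, ...]
) -> dict[float, SparseGraph]:
    """Sparsify one matrix at every density of a grid.

    The edge ranking and spanning tree are computed once; each density keeps
    the spanning tree plus the strongest non-tree edges, which also guarantees
    the nestedness of the resulting edge sets across the grid.
    """
    i, j, w = _matrix_edges(matrix)
    n = np.asarray(matrix).shape[0]
    n_possible = n * (n - 1) // 2
    order = _ascending_order(i, j, w)
    tree = _spanning_tree_mask(n, i, j, order)
    removable = order[~tree[order]]  # ascending removal order, non-tree edges only

    out: dict[float, SparseGraph] = {}
    for density in grid:
        if not 0.0 < density <= 1.0:
            raise ValueError(f"density must lie in (0, 1], got {density}")
        m = int(round(density * n_possible))
        if m < n - 1:
            raise ValueError(
                f"density {density} keeps {m} edges; a connected graph on {n} "
                f"nodes needs at least {n - 1}"
            )
        n_remove = i.shape[0] - m
        if n_remove <= 0:
            keep = np.ones(i.shape[0], dtype=bool)
            forced = False
        elif n_remove > removable.shape[0]:
            # only bridges remain before reaching the target count
            keep = tree.copy()
            forced = True
        else:
            keep = np.ones(i.shape[0], dtype=bool)
            keep[removable[:n_remove]] = False
            forced = False
        edges = np.column_stack([i[keep], j[keep]])
        out[density] = SparseGraph(
            n_nodes=n,
            edges=edges,
            weights=w[keep],
            target_density=density,
            bridge_forced=forced,
        )
    return out


def is_connected(graph: SparseGraph) -> bool:
    """Breadth-first reachability check."""
    if graph.n_nodes == 0:
        raise ValueError("empty node set")
    if graph.n_nodes == 1:
        return True
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    m = coo_matrix(
        (np.ones(graph.n_edges), (graph.edges[:, 0], graph.edges[:, 1])),
        shape=(graph.n_nodes, graph.n_nodes),
    )
    n_comp, _ = connected_components(m, directed=False)
    return n_comp == 1


def graph_density(graph: SparseGraph) -> float:
    """Fraction of possible edges present."""
    if graph.n_nodes == 0:
        raise ValueError("empty node set")
    possible = graph.n_nodes * (graph.n_nodes - 1) // 2
    return graph.n_edges / possible if possible else 0.0


def build_graph_ensemble(
    stacks,
    grid: list[float],
) -> dict[tuple[str, str, float], SparseGraph]:
    """One SparseGraph per (subject, condition, sparsity).

    ``stacks`` maps condition -> ConditionStack; the default grid is the nine
    densities 12% to 28% in steps of 2%.
    """
    ensemble: dict[tuple[str, str, float], SparseGraph] = {}
    for cond, stack in stacks.items():
        for sid, mat in zip(stack.subject_ids, stack.matrices):
            for density, g in sparsify_grid(mat.values, grid).items():
                ensemble[(sid, cond, density)] = g
    return ensemble
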
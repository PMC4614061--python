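"""Independent brute-force oracles used to verify the implementation.

Everything here is deliberately naive — exhaustive enumeration, literal
textbook formulas, per-step BFS — and shares no code with the package.
"""

from __future__ import annotations

import itertools
from collections import defaultdict

import numpy as np

TOL = 1e-10


# --- graph helpers ----------------------------------------------------------

def adjacency_from_edges(n: int, edges, weights) -> np.ndarray:
    A = np.zeros((n, n))
    for (i, j), w in zip(edges, weights):
        A[i, j] = A[j, i] = w
    return A


def floyd_warshall_lengths(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest path lengths on l = 1/w."""
    n = adj.shape[0]
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0.0)
    for i in range(n):
        for j in range(n):
            if adj[i, j] > 0:
                d[i, j] = 1.0 / adj[i, j]
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if d[i, k] + d[k, j] < d[i, j]:
                    d[i, j] = d[i, k] + d[k, j]
    return d


def oracle_degree_strength(n, edges, weights):
    deg = np.zeros(n, dtype=int)
    s = np.zeros(n)
    for (i, j), w in zip(edges, weights):
        deg[i] += 1
        deg[j] += 1
        s[i] += w
        s[j] += w
    return deg, s


def oracle_clustering(n, edges, weights):
    """Onnela weighted clustering by direct triple enumeration."""
    A = adjacency_from_edges(n, edges, weights)
    w_max = A.max()
    W = A / w_max if w_max > 0 else A
    c = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if A[i, j] > 0]
        k = len(nb)
        if k < 2:
            continue
        total = 0.0
        for j, h in itertools.combinations(nb, 2):
            if A[j, h] > 0:
                total += (W[i, j] * W[i, h] * W[j, h]) ** (1.0 / 3.0)
        c[i] = 2.0 * total / (k * (k - 1))
    return c


def oracle_efficiencies(n, edges, weights):
    """(global, local vector, lege vector) from Floyd-Warshall distances."""
    A = adjacency_from_edges(n, edges, weights)
    d = floyd_warshall_lengths(A)

    def eff(dist):
        m = dist.shape[0]
        if m < 2:
            return 0.0
        total = 0.0
        for i in range(m):
            for j in range(m):
                if i != j and np.isfinite(dist[i, j]) and dist[i, j] > 0:
                    total += 1.0 / dist[i, j]
        return total / (m * (m - 1))

    e_glob = eff(d)
    e_loc = np.zeros(n)
    for i in range(n):
        nb = [j for j in range(n) if A[i, j] > 0]
        if len(nb) < 2:
            continue
        sub = A[np.ix_(nb, nb)]
        e_loc[i] = eff(floyd_warshall_lengths(sub))
    return e_glob, e_loc, e_loc / e_glob


def oracle_betweenness(n, edges, weights):
    """Normalized betweenness by exhaustive simple-path enumeration."""
    A = adjacency_from_edges(n, edges, weights)

    def all_paths(s, t):
        paths = []

        def dfs(node, visited, length, path):
            if node == t:
                paths.append((length, list(path)))
                return
            for nxt in range(n):
                if A[node, nxt] > 0 and nxt not in visited:
                    visited.add(nxt)
                    path.append(nxt)
                    dfs(nxt, visited, length + 1.0 / A[node, nxt], path)
                    path.pop()
                    visited.remove(nxt)

        dfs(s, {s}, 0.0, [s])
        return paths

    bc = np.zeros(n)
    for s, t in itertools.combinations(range(n), 2):
        paths = all_paths(s, t)
        if not paths:
            continue
        best = min(p[0] for p in paths)
        geodesics = [p for l, p in paths if l <= best + TOL]
        sigma = len(geodesics)
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in geodesics if v in p)
            bc[v] += through / sigma
    norm = (n - 1) * (n - 2) / 2.0
    return bc / norm if norm > 0 else bc


def oracle_participation(n, edges, weights, partition):
    p = np.zeros(n)
    for i in range(n):
        s_m = defaultdict(float)
        for (a, b), w in zip(edges, weights):
            if a == i:
                s_m[partition[b]] += w
            elif b == i:
                s_m[partition[a]] += w
        s = sum(s_m.values())
        if s > 0:
            p[i] = 1.0 - sum((v / s) ** 2 for v in s_m.values())
    return p


def oracle_components(n, edge_list):
    """Union-find connected components of an edge list -> list of edge sets."""
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i, j in edge_list:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    groups = defaultdict(list)
    for i, j in edge_list:
        groups[find(i)].append((i, j))
    return sorted(groups.values(), key=len, reverse=True)


# --- naive sparsification ---------------------------------------------------

def _is_connected_edges(n, edges) -> bool:
    adj = defaultdict(set)
    for i, j in edges:
        adj[i].add(j)
        adj[j].add(i)
    seen = {0}
    stack = [0]
    while stack:
        u = stack.pop()
        for v in adj[u]:
            if v not in seen:
                seen.add(v)
                stack.append(v)
    return len(seen) == n


def naive_sparsify(matrix: np.ndarray, m: int):
    """Literal recursive weakest-edge removal with per-step connectivity check.

    Edges examined once, ascending by (weight, (i, j)); an edge whose removal
    disconnects the graph is retained and the next weakest tried instead.
    Returns the surviving edge set (frozenset of (i, j) pairs).
    """
    n = matrix.shape[0]
    edges = [
        (matrix[i, j], i, j)
        for i in range(n)
        for j in range(i + 1, n)
        if matrix[i, j] != 0.0
    ]
    edges.sort(key=lambda e: (e[0], e[1], e[2]))
    current = {(i, j) for _, i, j in edges}
    for w, i, j in edges:
        if len(current) <= m:
            break
        trial = current - {(i, j)}
        if _is_connected_edges(n, trial):
            current = trial
    return frozenset(current)


# --- statistics -------------------------------------------------------------

def wilcoxon_exact_two_sided(diffs: np.ndarray) -> float:
    """Exact two-sided signed-rank p by enumerating all 2^n sign assignments.

    Zero differences are dropped (the classic zero handling); average ranks
    for ties.
    """
    from scipy.stats import rankdata

    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = rankdata(np.abs(d))
    w_plus = ranks[d > 0].sum()
    w_minus = ranks[d < 0].sum()
    w_obs = min(w_plus, w_minus)
    count = 0
    for signs in itertools.product([0, 1], repeat=n):
        wp = sum(r for r, s in zip(ranks, signs) if s)
        wm = ranks.sum() - wp
        if min(wp, wm) <= w_obs + TOL:
            count += 1
    return count / 2**n


def bh_stepup(p_values, q):
    """Benjamini-Hochberg step-up by direct definition: reject mask."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= rank * q / m:
            k_max = rank
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_max]] = True
    return reject
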
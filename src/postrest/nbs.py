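"""Network-based statistic: edgewise paired tests, suprathreshold components,
permutation family-wise-error control, and the contrast battery.

The NBS asks whether any connected cluster of edges differs between two
conditions. Per edge, a one-sided paired t-statistic is computed on the
per-subject connectivity differences; edges with t >= tau (the primary
threshold) form a graph whose connected components are the candidate
subnetworks, sized by edge count ("extent"). Family-wise error is controlled
by permutation: subjects are their own controls across conditions, so the null
is generated by random sign flips of each subject's difference matrix; each
permutation contributes its maximal component size, and
p_fwe = (1 + #{null >= observed}) / (K + 1).

Because the test operates on the raw correlation matrices, its result does not
depend on any graph sparsification.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConditionStack

__all__ = [
    "NbsComponent",
    "NbsResult",
    "edgewise_paired_t",
    "suprathreshold_components",
    "nbs_permutation_test",
    "nbs_contrast_battery",
    "enumerate_contrasts",
    "pooled_stack",
]


@dataclass
class NbsComponent:
    """One suprathreshold connected component ("subnetwork")."""

    nodes: np.ndarray
    edges: np.ndarray  # (m, 2) node pairs, i < j
    p_fwe: float = 1.0

    @property
    def n_nodes(self) -> int:
        return int(self.nodes.shape[0])

    @property
    def n_edges(self) -> int:
        return int(self.edges.shape[0])


@dataclass
class NbsResult:
    """Outcome of one NBS contrast at one primary threshold."""

    contrast: str
    tau: float
    components: list[NbsComponent] = field(default_factory=list)
    n_permutations: int = 0
    null_max_sizes: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def observed_size(self) -> int:
        return self.components[0].n_edges if self.components else 0

    @property
    def p_fwe(self) -> float:
        return self.components[0].p_fwe if self.components else 1.0

    @property
    def largest_component(self) -> NbsComponent | None:
        return self.components[0] if self.components else None


def _stack_diffs(stack_a: ConditionStack, stack_b: ConditionStack) -> np.ndarray:
    """(n_subjects, n_edges) per-subject differences on the upper triangle."""
    if stack_a.subject_ids != stack_b.subject_ids:
        raise ValueError("stacks must share subject order")
    A = stack_a.as_array()
    B = stack_b.as_array()
    n = A.shape[1]
    iu, ju = np.triu_indices(n, k=1)
    return A[:, iu, ju] - B[:, iu, ju]


def _paired_t_from_diffs(diffs: np.ndarray) -> np.ndarray:
    """Paired t per column of an (n, E) difference array.

    Zero-variance nonzero differences give signed infinity (suprathreshold in
    their direction); identically-zero columns give t = 0.
    """
    n = diffs.shape[0]
    if n < 3:
        raise ValueError("paired t needs at least 3 subjects")
    mean = diffs.mean(axis=0)
    sd = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
        t = np.where(sd == 0, np.where(mean == 0, 0.0, np.sign(mean) * np.inf), t)
    return t


def edgewise_paired_t(stack_a: ConditionStack, stack_b: ConditionStack) -> np.ndarray:
    """Symmetric matrix of one-sided paired t statistics for A - B."""
    diffs = _stack_diffs(stack_a, stack_b)
    n_rois = stack_a.matrices[0].n_rois
    t = np.zeros((n_rois, n_rois))
    iu, ju = np.triu_indices(n_rois, k=1)
    tvals = _paired_t_from_diffs(diffs)
    t[iu, ju] = tvals
    t[ju, iu] = tvals
    return t


def _components_from_edges(
    n_nodes: int, edge_i: np.ndarray, edge_j: np.ndarray
) -> list[NbsComponent]:
    """Connected components of an edge list, sorted by edge count descending."""
    if edge_i.size == 0:
        return []
    from scipy.sparse import coo_matrix
    from scipy.sparse.csgraph import connected_components

    adj = coo_matrix(
        (np.ones(edge_i.size), (edge_i, edge_j)), shape=(n_nodes, n_nodes)
    )
    _, labels = connected_components(adj, directed=False)
    comp_of_edge = labels[edge_i]
    comps = []
    for lbl in np.unique(comp_of_edge):
        mask = comp_of_edge == lbl
        edges = np.column_stack([edge_i[mask], edge_j[mask]])
        nodes = np.unique(edges)
        comps.append(NbsComponent(nodes=nodes, edges=edges))
    comps.sort(key=lambda c: (-c.n_edges, int(c.nodes.min())))
    return comps


def suprathreshold_components(t_matrix: np.ndarray, tau: float) -> list[NbsComponent]:
    """Connected components of the graph of edges with t >= tau."""
    if tau <= 0:
        raise ValueError("primary threshold tau must be positive")
    n = t_matrix.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    mask = t_matrix[iu, ju] >= tau
    return _components_from_edges(n, iu[mask], ju[mask])


def _max_null_sizes(
    diffs: np.ndarray,
    n_nodes: int,
    taus: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """(len(taus), K) maximal component sizes under the sign-flip null.

    Sign flips leave per-edge squared sums unchanged, so each permutation's t
    vector needs only the flipped means — one matrix product for all
    permutations.
    """
    n, n_edges = diffs.shape
    iu, ju = np.triu_indices(n_nodes, k=1)
    signs = rng.choice([-1.0, 1.0], size=(n_permutations, n))
    means = signs @ diffs / n
    ss = (diffs**2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        var = (ss - n * means**2) / (n - 1)
        var = np.clip(var, 0.0, None)
        t_perm = means / np.sqrt(var / n)
        t_perm = np.where(
            var == 0, np.where(means == 0, 0.0, np.sign(means) * np.inf), t_perm
        )
    out = np.zeros((taus.size, n_permutations), dtype=int)
    for k in range(n_permutations):
        trow = t_perm[k]
        for ti, tau in enumerate(taus):
            mask = trow >= tau
            if not mask.any():
                continue
            comps = _components_from_edges(n_nodes, iu[mask], ju[mask])
            out[ti, k] = comps[0].n_edges
    return out


def nbs_permutation_test(
    stack_a: ConditionStack,
    stack_b: ConditionStack,
    tau: float,
    n_permutations: int = 5000,
    seed: int = 0,
    contrast: str = "A > B",
) -> NbsResult:
    """NBS for the one-sided contrast A > B at primary threshold ``tau``."""
    if n_permutations < 1:
        raise ValueError("need at least one permutation")
    diffs = _stack_diffs(stack_a, stack_b)
    n_nodes = stack_a.matrices[0].n_rois
    t = _paired_t_from_diffs(diffs)
    iu, ju = np.triu_indices(n_nodes, k=1)
    mask = t >= tau
    comps = _components_from_edges(n_nodes, iu[mask], ju[mask])
    rng = np.random.default_rng(seed)
    null = _max_null_sizes(diffs, n_nodes, np.array([tau]), n_permutations, rng)[0]
    for comp in comps:
        comp.p_fwe = (1.0 + np.sum(null >= comp.n_edges)) / (n_permutations + 1.0)
    return NbsResult(
        contrast=contrast,
        tau=tau,
        components=comps,
        n_permutations=n_permutations,
        null_max_sizes=null,
    )


def pooled_stack(stacks: dict[str, ConditionStack], conditions: list[str], label: str) -> ConditionStack:
    """Per-subject mean of several conditions' matrices, as a pseudo-condition."""
    from .connectivity import ConnectivityMatrix

    base = stacks[conditions[0]]
    arrays = [stacks[c].as_array() for c in conditions]
    for c in conditions[1:]:
        if stacks[c].subject_ids != base.subject_ids:
            raise ValueError("stacks must share subject order")
    mean = np.mean(arrays, axis=0)
    mats = [
        ConnectivityMatrix(values=mean[k], subject_id=sid, condition=label)
        for k, sid in enumerate(base.subject_ids)
    ]
    return ConditionStack(condition=label, subject_ids=list(base.subject_ids), matrices=mats)


def enumerate_contrasts(
    conditions: list[str], baseline: str
) -> list[tuple[str, str, str]]:
    """All directed contrasts: baseline vs pooled narratives, baseline vs each
    narrative, and every narrative pair — both directions each.

    Returns (label, condition_a, condition_b) with the pooled pseudo-condition
    named ``all_narratives``.
    """
    narratives = [c for c in conditions if c != baseline]
    pairs: list[tuple[str, str]] = []
    if len(narratives) > 1:
        pairs.append((baseline, "all_narratives"))
    pairs.extend((baseline, c) for c in narratives)
    for a_idx in range(len(narratives)):
        for b_idx in range(a_idx + 1, len(narratives)):
            pairs.append((narratives[a_idx], narratives[b_idx]))
    out = []
    for a, b in pairs:
        out.append((f"{a} > {b}", a, b))
        out.append((f"{b} > {a}", b, a))
    return out


def nbs_contrast_battery(
    stacks: dict[str, ConditionStack],
    taus: list[float],
    baseline: str,
    n_permutations: int = 5000,
    alpha: float = 0.0125,
    seed: int = 0,
):
    """Run every directed contrast over the primary-threshold sweep.

    Permutation sign flips are shared across thresholds within a contrast (the
    same flipped t map is thresholded at each tau). Returns a tidy DataFrame
    with one row per (contrast, tau): p_fwe, component sizes, significance at
    the Bonferroni-adjusted alpha — plus the component objects keyed by
    (contrast, tau) for downstream overlap analysis.
    """
    import pandas as pd

    contrasts = enumerate_contrasts(sorted(stacks), baseline)
    work = dict(stacks)
    narratives = [c for c in sorted(stacks) if c != baseline]
    if len(narratives) > 1:
        work["all_narratives"] = pooled_stack(stacks, narratives, "all_narratives")

    taus_arr = np.asarray(sorted(taus), dtype=float)
    rows = []
    components: dict[tuple[str, float], NbsComponent | None] = {}
    for c_idx, (label, cond_a, cond_b) in enumerate(contrasts):
        diffs = _stack_diffs(work[cond_a], work[cond_b])
        n_nodes = work[cond_a].matrices[0].n_rois
        t = _paired_t_from_diffs(diffs)
        iu, ju = np.triu_indices(n_nodes, k=1)
        rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(c_idx,)))
        null = _max_null_sizes(diffs, n_nodes, taus_arr, n_permutations, rng)
        for ti, tau in enumerate(taus_arr):
            mask = t >= tau
            comps = _components_from_edges(n_nodes, iu[mask], ju[mask])
            for comp in comps:
                comp.p_fwe = (1.0 + np.sum(null[ti] >= comp.n_edges)) / (
                    n_permutations + 1.0
                )
            top = comps[0] if comps else None
            components[(label, float(tau))] = top
            rows.append(
                {
                    "contrast": label,
                    "tau": float(tau),
                    "p_fwe": top.p_fwe if top else 1.0,
                    "n_nodes": top.n_nodes if top else 0,
                    "n_edges": top.n_edges if top else 0,
                    "significant": bool(top and top.p_fwe < alpha),
                }
            )
    return pd.DataFrame(rows), components
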
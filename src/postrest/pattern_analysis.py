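"""Edge-consistency profile of a focal node and overlap statistics.

For a focal node (the hub of interest), the consistency profile records, per
condition and potential partner ROI, the fraction of subjects whose sparsified
graph (single stated density, default 18%) contains the focal-partner edge.
Partners reaching an absolute subject-count threshold (default at least 13)
are the node's "consistent neighbors" in that condition. The overlap of such a
neighbor set with the node set of an NBS subnetwork is assessed against random
draws without replacement via the hypergeometric upper tail; the simpler
all-draws-marked product form is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .graph_build import SparseGraph

__all__ = [
    "ConsistencyProfile",
    "edge_consistency",
    "consistent_neighbors",
    "overlap_probability",
    "OverlapProbability",
]


@dataclass
class ConsistencyProfile:
    """Per (condition, partner) edge-occurrence counts for one focal node."""

    focal_node: int
    sparsity: float
    n_subjects: int
    table: pd.DataFrame  # columns: condition, partner, n_with_edge, pct_subjects


def edge_consistency(
    graphs: dict[tuple[str, str], SparseGraph],
    focal_node: int,
    sparsity: float = 0.18,
) -> ConsistencyProfile:
    """Count, per condition and partner, the subjects whose graph has the edge.

    ``graphs`` maps (subject, condition) to the SparseGraph built at the
    stated density. Percentages are over the number of subjects per condition.
    """
    if not graphs:
        raise ValueError("no graphs supplied")
    n_nodes = next(iter(graphs.values())).n_nodes
    if not 0 <= focal_node < n_nodes:
        raise ValueError(f"focal node {focal_node} outside 0..{n_nodes - 1}")
    conditions = sorted({cond for _, cond in graphs})
    subjects = sorted({sid for sid, _ in graphs})
    counts = {cond: np.zeros(n_nodes, dtype=int) for cond in conditions}
    for (sid, cond), g in graphs.items():
        mask = (g.edges == focal_node).any(axis=1)
        partners = g.edges[mask].ravel()
        partners = partners[partners != focal_node]
        counts[cond][partners] += 1
    rows = []
    for cond in conditions:
        for partner in range(n_nodes):
            if partner == focal_node:
                continue
            c = int(counts[cond][partner])
            rows.append(
                {
                    "condition": cond,
                    "partner": partner,
                    "n_with_edge": c,
                    "pct_subjects": 100.0 * c / len(subjects),
                }
            )
    return ConsistencyProfile(
        focal_node=focal_node,
        sparsity=sparsity,
        n_subjects=len(subjects),
        table=pd.DataFrame(rows),
    )


def consistent_neighbors(
    profile: ConsistencyProfile, condition: str, min_subjects: int = 13
) -> set[int]:
    """Partners whose edge occurs in at least ``min_subjects`` subjects."""
    if min_subjects > profile.n_subjects:
        raise ValueError(
            f"min_subjects {min_subjects} exceeds the {profile.n_subjects} subjects"
        )
    sub = profile.table[profile.table["condition"] == condition]
    if sub.empty:
        raise ValueError(f"condition {condition!r} not in profile")
    return set(sub.loc[sub["n_with_edge"] >= min_subjects, "partner"].astype(int))


@dataclass
class OverlapProbability:
    """Tail probability of an observed set overlap under random draws.

    ``hypergeometric_tail`` is P(X >= overlap) for X hypergeometric
    (``set_b_size`` draws from ``n_total`` items of which ``set_a_size`` are
    marked). ``sequential_product`` is the probability that the first
    ``overlap`` draws are all marked, prod_{k<overlap} (a - k) / (N - k) — the
    simpler "all draws marked" form.
    """

    hypergeometric_tail: float
    sequential_product: float


def overlap_probability(
    n_total: int, set_a_size: int, set_b_size: int, overlap: int
) -> OverlapProbability:
    """Chance of drawing ``overlap`` marked items without replacement."""
    if not (
        0 <= overlap <= min(set_a_size, set_b_size)
        and set_a_size <= n_total
        and set_b_size <= n_total
    ):
        raise ValueError("inconsistent counts for overlap probability")
    tail = float(stats.hypergeom.sf(overlap - 1, n_total, set_a_size, set_b_size))
    product = 1.0
    for k in range(overlap):
        product *= (set_a_size - k) / (n_total - k)
    return OverlapProbability(hypergeometric_tail=tail, sequential_product=product)
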
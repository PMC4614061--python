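"""Dynamic (windowed) connectivity: nonoverlapping intervals, per-interval
graph metrics, baseline normalization, and per-interval condition tests.

The cleaned series is cut into ``n_intervals`` contiguous, equal-length,
nonoverlapping windows (floor division; trailing remainder volumes dropped:
230 volumes -> 3 x 76). Filtering is done once on the full series before
cutting — re-filtering a 76-volume window at 0.01 Hz would be ill-posed.
Per interval, connectivity and a sparse graph (default 18% density) are
rebuilt and degree and strength recorded for all nodes. For interpretability,
values are normalized by subtracting the baseline condition's group mean per
interval, which makes the baseline group mean exactly zero and leaves
between-condition differences untouched.
"""

from __future__ import annotations

import warnings
from dataclasses import replace

import numpy as np
import pandas as pd

from .connectivity import pearson_matrix
from .graph_build import sparsify_preserving_connectivity
from .group_stats import fdr_bh, shapiro_gate, _pair_test
from .nodal_metrics import degree_and_strength
from .preprocess import SubjectTimeseries

__all__ = [
    "split_intervals",
    "interval_metrics",
    "baseline_normalize",
    "interval_condition_tests",
]

DYNAMIC_METRICS = ["degree", "strength"]


def split_intervals(ts: SubjectTimeseries, n_intervals: int = 3) -> list[SubjectTimeseries]:
    """Cut a cleaned series into equal nonoverlapping contiguous intervals."""
    if n_intervals < 1:
        raise ValueError("n_intervals must be >= 1")
    if n_intervals == 1:
        return [ts]
    length = ts.n_volumes // n_intervals
    if length < 3:
        raise ValueError(
            f"{ts.n_volumes} volumes cannot form {n_intervals} intervals of >= 3 volumes"
        )
    return [
        replace(ts, data=ts.data[k * length : (k + 1) * length].copy())
        for k in range(n_intervals)
    ]


def interval_metrics(
    cleaned: dict[tuple[str, str], SubjectTimeseries],
    n_intervals: int = 3,
    sparsity: float = 0.18,
) -> pd.DataFrame:
    """Degree and strength per (subject, condition, interval, node).

    ``cleaned`` maps (subject, condition) to an already-preprocessed series.
    Each interval gets its own Pearson matrix and connectedness-preserving
    sparse graph at the stated density.
    """
    rows = []
    for (sid, cond) in sorted(cleaned):
        pieces = split_intervals(cleaned[(sid, cond)], n_intervals)
        for k, piece in enumerate(pieces, start=1):
            mat = pearson_matrix(piece, window=f"interval {k}")
            g = sparsify_preserving_connectivity(mat.values, sparsity)
            deg, stren = degree_and_strength(g)
            rows.append(
                pd.DataFrame(
                    {
                        "subject": sid,
                        "condition": cond,
                        "interval": k,
                        "node": np.arange(g.n_nodes),
                        "degree": deg,
                        "strength": stren,
                    }
                )
            )
    table = pd.concat(rows, ignore_index=True)
    table.attrs["sparsity"] = sparsity
    table.attrs["n_intervals"] = n_intervals
    return table


def baseline_normalize(table: pd.DataFrame, baseline: str = "baseline") -> pd.DataFrame:
    """Subtract the baseline condition's group mean per (interval, node).

    After normalization the baseline group mean is exactly zero in every
    interval; differences between conditions are unchanged (shift invariance).
    """
    if baseline not in set(table["condition"]):
        raise ValueError(f"baseline condition {baseline!r} missing from table")
    out = table.copy()
    base = table[table["condition"] == baseline]
    for metric in DYNAMIC_METRICS:
        means = base.groupby(["interval", "node"])[metric].mean()
        keys = list(zip(out["interval"], out["node"]))
        out[metric] = out[metric].to_numpy(dtype=float) - means.loc[keys].to_numpy()
    out.attrs.update(table.attrs)
    return out


def interval_condition_tests(
    table: pd.DataFrame,
    node: int,
    baseline: str = "baseline",
    alpha: float = 0.05,
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Pairwise narrative-condition tests per interval for one node.

    Paired t-tests are used when each cell's values pass a Shapiro-Wilk gate
    (the expected case for interval-level degree/strength); otherwise the
    routine warns and falls back to the Wilcoxon signed-rank test. The
    Benjamini-Hochberg correction runs over the whole family
    (condition pair x interval x metric).
    """
    metrics = metrics or DYNAMIC_METRICS
    sub = table[table["node"] == node]
    if sub.empty:
        raise ValueError(f"node {node} not present in table")
    narratives = sorted(c for c in sub["condition"].unique() if c != baseline)
    intervals = sorted(sub["interval"].unique())

    samples = {}
    for metric in metrics:
        for cond in narratives:
            for k in intervals:
                key = f"{metric}/{cond}/interval{k}"
                samples[key] = sub.query("condition == @cond and interval == @k")[
                    metric
                ].to_numpy()
    normal = all(shapiro_gate(samples, alpha=alpha).values())
    kind = "paired_t" if normal else "wilcoxon_signed_rank"
    if not normal:
        warnings.warn(
            "interval metrics failed the normality gate; using Wilcoxon "
            "signed-rank instead of paired t",
            stacklevel=2,
        )

    rows = []
    for metric in metrics:
        for k in intervals:
            cell = sub[sub["interval"] == k].pivot(
                index="subject", columns="condition", values=metric
            )
            for a_idx in range(len(narratives)):
                for b_idx in range(a_idx + 1, len(narratives)):
                    a, b = narratives[a_idx], narratives[b_idx]
                    stat, p = _pair_test(
                        cell[a].to_numpy(), cell[b].to_numpy(), kind
                    )
                    rows.append(
                        {
                            "metric": metric,
                            "interval": k,
                            "condition_a": a,
                            "condition_b": b,
                            "test": kind,
                            "statistic": stat,
                            "p": p,
                        }
                    )
    result = pd.DataFrame(rows)
    adj, reject = fdr_bh(result["p"].to_numpy(), q=alpha)
    result["p_corrected"] = adj
    result["reject"] = reject
    result.attrs["fdr_family_size"] = len(result)
    return result
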
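"""Group-level statistics on nodal metrics: normality gate, nonparametric
omnibus and post hoc tests, and multiple-comparison corrections.

The repeated-measures design (every subject contributes all conditions) is
screened with a Shapiro-Wilk normality gate; when any group fails, the
nonparametric route is taken: a Friedman rank-sum omnibus (paired) or
Kruskal-Wallis (independent-samples variant), followed by pairwise post hoc
tests (Wilcoxon signed-rank / Mann-Whitney U / paired t). Correction is either
Bonferroni over the condition pairs or Benjamini-Hochberg FDR over the tested
ROIs, matching the two correction families used at the omnibus and post hoc
levels respectively.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "shapiro_gate",
    "omnibus_condition_test",
    "pairwise_posthoc",
    "fdr_bh",
]


def shapiro_gate(samples: dict[str, np.ndarray], alpha: float = 0.05) -> dict[str, bool]:
    """Shapiro-Wilk normality flag per group (True = consistent with normal).

    A constant sample has no distributional shape to test; by convention it is
    flagged non-normal, which routes the pipeline to the nonparametric tests.
    """
    flags: dict[str, bool] = {}
    for name, x in samples.items():
        x = np.asarray(x, dtype=float)
        if x.size < 3:
            raise ValueError(f"group {name!r} needs at least 3 observations")
        if np.ptp(x) == 0:
            flags[name] = False
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, p = stats.shapiro(x)
        flags[name] = bool(p >= alpha)
    return flags


def _metric_value_columns(table: pd.DataFrame) -> list[str]:
    keys = {"subject", "condition", "sparsity", "node", "interval", "global_efficiency"}
    return [
        c
        for c in table.columns
        if c not in keys and pd.api.types.is_numeric_dtype(table[c])
    ]


def omnibus_condition_test(
    table: pd.DataFrame,
    kind: str = "friedman",
    metrics: list[str] | None = None,
) -> pd.DataFrame:
    """Omnibus condition effect per (metric, sparsity, node).

    ``table`` is the long-format nodal metrics table. ``friedman`` treats
    conditions as repeated measures (requires every subject in every
    condition); ``kruskal`` treats them as independent groups. Identical
    values across all conditions yield statistic 0 and p = 1.
    """
    if kind not in {"friedman", "kruskal"}:
        raise ValueError("kind must be 'friedman' or 'kruskal'")
    metrics = metrics or _metric_value_columns(table)
    conditions = sorted(table["condition"].unique())
    if len(conditions) < 2:
        raise ValueError("need at least two conditions")
    rows = []
    for (sparsity, node), chunk in table.groupby(["sparsity", "node"], sort=True):
        pivots = {
            m: chunk.pivot(index="subject", columns="condition", values=m)
            for m in metrics
        }
        for m, pivot in pivots.items():
            if pivot.isna().any().any():
                raise ValueError("friedman requires every subject in every condition")
            groups = [pivot[c].to_numpy() for c in conditions]
            stat, p = _omnibus(groups, kind)
            rows.append(
                {
                    "metric": m,
                    "sparsity": sparsity,
                    "node": node,
                    "test": kind,
                    "statistic": stat,
                    "p": p,
                }
            )
    return pd.DataFrame(rows)


def _omnibus(groups: list[np.ndarray], kind: str) -> tuple[float, float]:
    flat = np.concatenate(groups)
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    try:
        if kind == "friedman":
            stat, p = stats.friedmanchisquare(*groups)
        else:
            stat, p = stats.kruskal(*groups)
    except ValueError:
        return 0.0, 1.0
    if not np.isfinite(p) or not np.isfinite(stat):
        # degenerate ranks (e.g. all-tied data): no evidence of an effect
        return 0.0, 1.0
    return float(stat), float(p)


def _pair_test(x: np.ndarray, y: np.ndarray, kind: str) -> tuple[float, float]:
    d = x - y
    if kind == "wilcoxon_signed_rank":
        if np.all(d == 0):
            return 0.0, 1.0
        stat, p = stats.wilcoxon(x, y, zero_method="wilcox", method="auto")
    elif kind == "mann_whitney_u":
        if np.ptp(np.concatenate([x, y])) == 0:
            return 0.0, 1.0
        stat, p = stats.mannwhitneyu(x, y, alternative="two-sided")
    elif kind == "paired_t":
        if np.ptp(d) == 0:
            return 0.0, 1.0 if d[0] == 0 else 0.0
        stat, p = stats.ttest_rel(x, y)
    else:
        raise ValueError(f"unknown post hoc test {kind!r}")
    return float(stat), float(p)


def pairwise_posthoc(
    table: pd.DataFrame,
    kind: str = "wilcoxon_signed_rank",
    correction: str = "fdr_bh",
    alpha: float = 0.05,
    metrics: list[str] | None = None,
    nodes: list[int] | None = None,
) -> pd.DataFrame:
    """All pairwise condition comparisons per (metric, sparsity, node).

    ``nodes`` optionally restricts testing to omnibus-significant nodes.
    Correction scope follows the design of the two families it mirrors:
    ``bonferroni`` multiplies p by the number of condition pairs (within each
    metric/sparsity/node), while ``fdr_bh`` applies the Benjamini-Hochberg
    step-up across the tested ROIs (within each metric/sparsity/pair).
    """
    if correction not in {"bonferroni", "fdr_bh"}:
        raise ValueError("correction must be 'bonferroni' or 'fdr_bh'")
    metrics = metrics or _metric_value_columns(table)
    work = table if nodes is None else table[table["node"].isin(nodes)]
    conditions = sorted(work["condition"].unique())
    pairs = list(itertools.combinations(conditions, 2))
    rows = []
    for (sparsity, node), chunk in work.groupby(["sparsity", "node"], sort=True):
        for m in metrics:
            pivot = chunk.pivot(index="subject", columns="condition", values=m)
            for a, b in pairs:
                x, y = pivot[a].to_numpy(), pivot[b].to_numpy()
                stat, p = _pair_test(x, y, kind)
                rows.append(
                    {
                        "metric": m,
                        "sparsity": sparsity,
                        "node": node,
                        "condition_a": a,
                        "condition_b": b,
                        "test": kind,
                        "statistic": stat,
                        "p": p,
                    }
                )
    result = pd.DataFrame(rows)
    if result.empty:
        result["p_corrected"] = []
        result["reject"] = []
        return result
    if correction == "bonferroni":
        result["p_corrected"] = np.minimum(result["p"] * len(pairs), 1.0)
    else:
        result["p_corrected"] = np.nan
        for _, idx in result.groupby(
            ["metric", "sparsity", "condition_a", "condition_b"]
        ).groups.items():
            adj, _ = fdr_bh(result.loc[idx, "p"].to_numpy(), q=alpha)
            result.loc[idx, "p_corrected"] = adj
    result["reject"] = result["p_corrected"] < alpha
    return result


def fdr_bh(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up FDR: (adjusted p, reject mask)."""
    from statsmodels.stats.multitest import multipletests

    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy(), np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return p_adj, reject
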
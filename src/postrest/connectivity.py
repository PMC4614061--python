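"""Pearson functional-connectivity matrices and per-condition subject stacks."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .preprocess import SubjectTimeseries

__all__ = ["ConnectivityMatrix", "ConditionStack", "pearson_matrix", "assemble_condition_stacks"]


@dataclass
class ConnectivityMatrix:
    """Symmetric ROI x ROI Pearson correlation matrix with unit diagonal."""

    values: np.ndarray
    subject_id: str = ""
    condition: str = ""
    window: str = "full"

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("connectivity matrix must be square")
        if not np.allclose(V, V.T, atol=1e-12):
            raise ValueError("connectivity matrix must be symmetric within 1e-12")
        if np.any(np.abs(V) > 1.0 + 1e-9):
            raise ValueError("Pearson correlations must lie in [-1, 1]")
        V = np.clip((V + V.T) / 2.0, -1.0, 1.0)
        np.fill_diagonal(V, 1.0)
        self.values = V

    @property
    def n_rois(self) -> int:
        return self.values.shape[0]


@dataclass
class ConditionStack:
    """Connectivity matrices for one condition, subject order fixed."""

    condition: str
    subject_ids: list[str]
    matrices: list[ConnectivityMatrix] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.subject_ids) != len(self.matrices):
            raise ValueError("one matrix per subject required")

    def as_array(self) -> np.ndarray:
        """(n_subjects, N, N) array in the stack's subject order."""
        return np.stack([m.values for m in self.matrices])

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


def pearson_matrix(ts: SubjectTimeseries, window: str = "full") -> ConnectivityMatrix:
    """Pair-wise Pearson correlation of the ROI time series.

    Zero-variance ROIs cannot be correlated; the error names the first
    offending ROI label (or column index when no labels are attached).
    """
    data = ts.data
    if data.shape[0] < 3:
        raise ValueError("need at least 3 volumes for a correlation matrix")
    sd = data.std(axis=0)
    if np.any(sd == 0):
        idx = int(np.argmax(sd == 0))
        label = ts.roi_labels[idx] if ts.roi_labels else f"column {idx}"
        raise ValueError(f"zero-variance ROI: {label}")
    r = np.corrcoef(data, rowvar=False)
    r = np.clip((r + r.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(
        values=r, subject_id=ts.subject_id, condition=ts.condition, window=window
    )


def assemble_condition_stacks(
    matrices: dict[tuple[str, str], ConnectivityMatrix],
    conditions: list[str],
    included_subjects: list[str],
) -> dict[str, ConditionStack]:
    """Align per-(subject, condition) matrices into per-condition stacks.

    ``included_subjects`` is the QC-passing roster; a subject excluded in any
    condition must already have been dropped from it, so stacks share one
    subject order. Missing matrices are an error.
    """
    stacks: dict[str, ConditionStack] = {}
    order = sorted(included_subjects)
    for cond in conditions:
        mats = []
        for sid in order:
            key = (sid, cond)
            if key not in matrices:
                raise KeyError(f"missing connectivity matrix for subject {sid!r}, condition {cond!r}")
            mats.append(matrices[key])
        stacks[cond] = ConditionStack(condition=cond, subject_ids=list(order), matrices=mats)
    return stacks
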
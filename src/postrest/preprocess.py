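"""ROI time-series preprocessing: volume discard, motion QC, nuisance regression,
band-pass filtering.

The pipeline mirrors the common resting-state fMRI cleanup chain applied to
region-level BOLD signals: the first volumes are discarded to let longitudinal
magnetization reach equilibrium, subjects with excessive head motion are excluded,
nuisance signals (polynomial trend, six rigid-body motion parameters, white-matter
and CSF signals) are regressed out per ROI, and the residuals are band-pass
filtered to the low-frequency band that carries resting-state fluctuations
(0.01-0.08 Hz by default).

Order of operations is nuisance regression first, then the band-pass filter; the
filter is an ideal (frequency-domain) filter so that filtering is idempotent and
bit-reproducible. Global-signal regression and spatial smoothing are deliberately
not part of this chain.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SubjectTimeseries",
    "MotionTrace",
    "QcReport",
    "discard_initial_volumes",
    "motion_qc",
    "regress_nuisance",
    "bandpass",
    "build_confound_matrix",
]

RAD2DEG = 180.0 / math.pi


@dataclass
class SubjectTimeseries:
    """A volumes x ROIs BOLD matrix for one subject in one condition.

    ``stage`` tracks provenance through the pipeline (``raw`` straight from disk
    or the simulator, ``cleaned`` after regression + filtering).
    """

    data: np.ndarray
    tr_seconds: float
    subject_id: str = ""
    condition: str = ""
    stage: str = "raw"
    roi_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("time series must be a 2-D volumes x ROIs matrix")
        if self.data.shape[0] < 3:
            raise ValueError("time series needs at least 3 volumes")
        if not np.all(np.isfinite(self.data)):
            raise ValueError(
                f"non-finite values in time series for subject "
                f"{self.subject_id!r} condition {self.condition!r}"
            )
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")

    @property
    def n_volumes(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]


@dataclass
class MotionTrace:
    """Per-volume rigid-body motion: 3 translations (mm), 3 rotations (radians).

    The on-disk dialect is the SPM ``rp_*.txt`` convention; rotations stay in
    radians internally and are converted to degrees only for QC reporting.
    """

    params: np.ndarray
    subject_id: str = ""
    condition: str = ""

    def __post_init__(self) -> None:
        self.params = np.asarray(self.params, dtype=float)
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError(
                f"motion trace must have 6 columns, got shape {self.params.shape}"
            )
        if not np.all(np.isfinite(self.params)):
            raise ValueError("non-finite values in motion trace")

    @property
    def n_volumes(self) -> int:
        return self.params.shape[0]

    def max_translation_mm(self) -> float:
        return float(np.max(np.abs(self.params[:, :3]))) if self.params.size else 0.0

    def max_rotation_deg(self) -> float:
        if not self.params.size:
            return 0.0
        return float(np.max(np.abs(self.params[:, 3:])) * RAD2DEG)


@dataclass
class QcReport:
    """Head-motion quality control verdict for one subject in one condition."""

    subject_id: str
    condition: str
    max_translation_mm: float
    max_rotation_deg: float
    max_trans_threshold_mm: float
    max_rot_threshold_deg: float

    @property
    def passed(self) -> bool:
        return (
            self.max_translation_mm <= self.max_trans_threshold_mm
            and self.max_rotation_deg <= self.max_rot_threshold_deg
        )


def discard_initial_volumes(ts: SubjectTimeseries, n: int = 10) -> SubjectTimeseries:
    """Drop the first ``n`` volumes (magnetization-equilibrium discard)."""
    if n < 0:
        raise ValueError("n must be >= 0")
    if n == 0:
        return ts
    if ts.n_volumes <= n:
        raise ValueError(
            f"cannot discard {n} volumes from a series of {ts.n_volumes}"
        )
    return replace(ts, data=ts.data[n:].copy())


def motion_qc(
    trace: MotionTrace,
    max_trans_mm: float = 1.0,
    max_rot_deg: float = 1.0,
) -> QcReport:
    """Evaluate maximal head motion against exclusion thresholds.

    Maxima are taken over all volumes and axes; translations in mm, rotations
    converted from radians to degrees. A subject failing in any condition is
    meant to be excluded from every analysis (the orchestrator enforces this).
    """
    return QcReport(
        subject_id=trace.subject_id,
        condition=trace.condition,
        max_translation_mm=trace.max_translation_mm(),
        max_rotation_deg=trace.max_rotation_deg(),
        max_trans_threshold_mm=max_trans_mm,
        max_rot_threshold_deg=max_rot_deg,
    )


def build_confound_matrix(
    n_volumes: int,
    motion: np.ndarray | None = None,
    wm: np.ndarray | None = None,
    csf: np.ndarray | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Assemble the nuisance design: intercept, linear trend, 6 motion, WM, CSF.

    Returns the design matrix and column names (used in rank-deficiency
    diagnostics). Any of motion/wm/csf may be omitted.
    """
    cols: list[np.ndarray] = [np.ones(n_volumes), np.linspace(-1.0, 1.0, n_volumes)]
    names = ["intercept", "trend"]
    if motion is not None:
        motion = np.asarray(motion, dtype=float)
        if motion.shape != (n_volumes, 6):
            raise ValueError("motion regressors must be volumes x 6")
        for k in range(6):
            cols.append(motion[:, k])
            names.append(f"motion_{k + 1}")
    if wm is not None:
        cols.append(np.asarray(wm, dtype=float).ravel())
        names.append("wm")
    if csf is not None:
        cols.append(np.asarray(csf, dtype=float).ravel())
        names.append("csf")
    return np.column_stack(cols), names


def regress_nuisance(
    ts: SubjectTimeseries,
    confounds: np.ndarray,
    column_names: list[str] | None = None,
) -> SubjectTimeseries:
    """Project out nuisance regressors by per-ROI ordinary least squares.

    The confound matrix must already contain an intercept column if mean removal
    is intended. Residuals are orthogonal to every confound column. A
    rank-deficient design is rejected, naming the collinear columns.
    """
    X = np.asarray(confounds, dtype=float)
    if X.ndim != 2 or X.shape[0] != ts.n_volumes:
        raise ValueError(
            f"confound matrix rows ({X.shape[0] if X.ndim == 2 else '?'}) must "
            f"equal the number of volumes ({ts.n_volumes})"
        )
    names = column_names or [f"col_{k}" for k in range(X.shape[1])]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # locate offending columns through the pivoted QR diagonal
        _, r, piv = _qr_pivot(X)
        tol = abs(r[0, 0]) * max(X.shape) * np.finfo(float).eps
        bad = sorted(piv[rank:]) if abs(r[0, 0]) > 0 else list(range(X.shape[1]))
        bad_names = [names[k] for k in bad]
        raise ValueError(f"rank-deficient nuisance design; collinear columns: {bad_names}")
    beta, *_ = np.linalg.lstsq(X, ts.data, rcond=None)
    resid = ts.data - X @ beta
    return replace(ts, data=resid, stage="cleaned")


def _qr_pivot(X: np.ndarray):
    from scipy.linalg import qr

    q, r, piv = qr(X, mode="economic", pivoting=True)
    return q, r, piv


def bandpass(
    ts: SubjectTimeseries,
    lo: float = 0.01,
    hi: float = 0.08,
) -> SubjectTimeseries:
    """Ideal frequency-domain band-pass filter.

    Discrete Fourier bins with frequency ``lo <= f <= hi`` are retained, all
    others (including DC) are zeroed, and the series is transformed back. The
    hard spectral mask makes the operation exactly idempotent, at the price of
    the usual ringing of ideal filters.
    """
    nyquist = 1.0 / (2.0 * ts.tr_seconds)
    if not 0 <= lo < hi:
        raise ValueError("need 0 <= lo < hi")
    if hi >= nyquist:
        raise ValueError(
            f"upper band edge {hi} Hz is not below the Nyquist frequency "
            f"{nyquist:.4f} Hz for TR {ts.tr_seconds}"
        )
    T = ts.n_volumes
    freqs = np.fft.rfftfreq(T, d=ts.tr_seconds)
    keep = (freqs >= lo) & (freqs <= hi)
    spectrum = np.fft.rfft(ts.data, axis=0)
    spectrum[~keep] = 0.0
    filtered = np.fft.irfft(spectrum, n=T, axis=0)
    return replace(ts, data=filtered, stage="cleaned")
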
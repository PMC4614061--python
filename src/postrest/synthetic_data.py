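"""Synthetic multi-subject, multi-condition ROI time-series generator.

Emulates the data layout of a repeated rest-task-rest fMRI study: every subject
is scanned once at baseline and once after each of three narrative conditions
(secure, dismissing, preoccupied), yielding ROI-level BOLD series of 240 volumes
at TR 2.61 s over 104 ROIs.

The generative model plants exactly the structure the downstream analyses are
built to detect:

* block/community correlation structure over the ROIs (``n_communities`` blocks
  with within/between correlations ``rho_within``/``rho_between``);
* a hub node connected to ~20 neighbor ROIs at elevated correlation ``rho_hub``
  (the synthetic analogue of a supplementary-motor-area hub);
* a condition-specific multiplicative reduction (factor ``effect_scale``) of a
  small hub-centered subnetwork of correlations in one condition (default: a
  9-node, 9-edge subnetwork reduced in the "dismissing" condition);
* optionally, restriction of that reduction to the volumes covering the first
  post-discard third of the scan (``dynamic_only``), so that windowed analyses
  see an effect that dissolves over time;
* nuisance contamination (linear trend, motion-correlated signal from a
  simulated 6-parameter rigid-body trace, white-matter and CSF proxy signals)
  that the preprocessing stage is expected to remove;
* band-limited temporal autocorrelation through AR(1) innovations; the
  downstream 0.01-0.08 Hz filter imposes the final spectral band.

Per-subject heterogeneity is a symmetric correlation perturbation (sd
``subject_jitter``) shared across a subject's conditions, so the paired design
carries genuine subject effects. Everything is deterministic in
(seed, subject, condition).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np

from .preprocess import MotionTrace, SubjectTimeseries

__all__ = [
    "SimulationSpec",
    "build_condition_targets",
    "nearest_psd",
    "simulate_subject",
    "simulate_study",
]

DEFAULT_CONDITIONS = ("baseline", "secure", "dismissing", "preoccupied")


@dataclass
class SimulationSpec:
    """Parameters of the synthetic study.

    Defaults reproduce the reference design: 23 subjects x 4 conditions,
    240 volumes, 104 ROIs in 8 communities, a hub with 20 neighbors and a
    9-node / 9-edge planted disconnection (hub-to-8-neighbors plus one
    neighbor-neighbor edge) scaled by ``effect_scale`` in the dismissing
    condition.
    """

    n_rois: int = 104
    n_subjects: int = 23
    n_volumes: int = 240
    tr_seconds: float = 2.61
    n_communities: int = 8
    rho_within: float = 0.4
    rho_between: float = 0.1
    hub_index: int = 0
    hub_neighbors: tuple[int, ...] = ()
    rho_hub: float = 0.45
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    effect_condition: str = "dismissing"
    effect_scale: float = 0.5
    effect_edges: tuple[tuple[int, int], ...] = ()
    dynamic_only: bool = False
    n_discard_volumes: int = 10
    effect_window_volumes: int = 76
    ar_coefficient: float = 0.3
    subject_jitter: float = 0.02
    trend_loading: float = 0.3
    motion_loading: float = 0.2
    wm_loading: float = 0.3
    csf_loading: float = 0.3
    plant_motion_outlier: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hub_neighbors:
            n_nb = min(20, self.n_rois - 1)
            self.hub_neighbors = tuple(
                i for i in range(self.n_rois) if i != self.hub_index
            )[:n_nb]
        if not self.effect_edges:
            nb = list(self.hub_neighbors)
            edges = [(self.hub_index, j) for j in nb[:8]]
            if len(nb) >= 2:
                edges.append((nb[0], nb[1]))
            self.effect_edges = tuple(
                (min(a, b), max(a, b)) for a, b in edges
            )
        self._validate()

    def _validate(self) -> None:
        for rho in (self.rho_within, self.rho_between, self.rho_hub):
            if not -1.0 < rho < 1.0:
                raise ValueError("correlations must lie in (-1, 1)")
        if not 0.0 < self.effect_scale <= 1.0:
            raise ValueError("effect_scale must lie in (0, 1]")
        if self.effect_condition not in self.conditions:
            raise ValueError(
                f"effect_condition {self.effect_condition!r} not in conditions"
            )
        if not 0 <= self.hub_index < self.n_rois:
            raise ValueError("hub_index out of range")
        hub_edge_nodes = {n for e in self.effect_edges for n in e}
        declared = set(self.hub_neighbors) | {self.hub_index}
        if not hub_edge_nodes <= declared:
            raise ValueError("effect_edges must connect the hub and its neighbors")
        if abs(self.ar_coefficient) >= 1.0:
            raise ValueError("ar_coefficient must satisfy |phi| < 1")

    def subject_ids(self) -> list[str]:
        return [f"sub-{k + 1:02d}" for k in range(self.n_subjects)]


def nearest_psd(matrix: np.ndarray, floor: float = 1e-8) -> np.ndarray:
    """Project a symmetric matrix to the positive-semidefinite cone.

    Eigenvalues below ``floor`` are clipped to ``floor``, the matrix is
    reassembled and rescaled to unit diagonal. If the input is already PSD
    (all eigenvalues >= floor) it is returned unchanged, which makes the
    operation exactly idempotent.
    """
    M = np.asarray(matrix, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise ValueError("nearest_psd expects a square matrix")
    if not np.allclose(M, M.T, atol=1e-10):
        raise ValueError("nearest_psd expects a symmetric matrix")
    vals, vecs = np.linalg.eigh(M)
    if vals.min() >= floor:
        return M.copy()
    vals = np.clip(vals, floor, None)
    out = (vecs * vals) @ vecs.T
    d = np.sqrt(np.diag(out))
    out = out / np.outer(d, d)
    out = (out + out.T) / 2.0
    np.fill_diagonal(out, 1.0)
    return out


def _baseline_target(spec: SimulationSpec) -> np.ndarray:
    n = spec.n_rois
    community = roi_communities(spec)
    same = community[:, None] == community[None, :]
    M = np.where(same, spec.rho_within, spec.rho_between).astype(float)
    hub = spec.hub_index
    for j in spec.hub_neighbors:
        M[hub, j] = M[j, hub] = spec.rho_hub
    np.fill_diagonal(M, 1.0)
    return M


def roi_communities(spec: SimulationSpec) -> np.ndarray:
    """Community label per ROI as used by the baseline correlation target."""
    n = spec.n_rois
    return np.minimum(np.arange(n) * spec.n_communities // n, spec.n_communities - 1)


def build_condition_targets(spec: SimulationSpec) -> dict[str, np.ndarray]:
    """Target correlation matrix per condition.

    All conditions share the baseline block-plus-hub structure; in the effect
    condition each planted edge's correlation is multiplied by
    ``effect_scale``. Each target is then projected to the PSD cone. The
    projection must not move any non-effect entry by more than 0.05, otherwise
    the requested structure is infeasible and an error is raised.
    """
    base = _baseline_target(spec)
    targets: dict[str, np.ndarray] = {}
    for cond in spec.conditions:
        raw = base.copy()
        if cond == spec.effect_condition and spec.effect_scale < 1.0:
            for i, j in spec.effect_edges:
                raw[i, j] *= spec.effect_scale
                raw[j, i] = raw[i, j]
        fixed = nearest_psd(raw)
        drift = np.abs(fixed - raw)
        for i, j in spec.effect_edges:
            drift[i, j] = drift[j, i] = 0.0
        if drift.max() > 0.05:
            raise ValueError(
                "PSD projection moved a non-effect correlation by "
                f"{drift.max():.3f} (> 0.05); simulation spec infeasible"
            )
        targets[cond] = fixed
    return targets


def _subject_rng(spec: SimulationSpec, subject_idx: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_idx,))
    )


def _subject_condition_rng(
    spec: SimulationSpec, subject_idx: int, cond_idx: int
) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=spec.seed, spawn_key=(subject_idx, cond_idx))
    )


def _subject_target(
    spec: SimulationSpec, target: np.ndarray, subject_idx: int
) -> np.ndarray:
    """Perturb the condition target with subject-specific symmetric noise.

    The perturbation is drawn from the subject-keyed stream, hence identical
    across that subject's conditions: planted condition differences survive.
    """
    if spec.subject_jitter <= 0:
        return target
    rng = _subject_rng(spec, subject_idx)
    n = spec.n_rois
    noise = rng.normal(0.0, spec.subject_jitter, size=(n, n))
    noise = (noise + noise.T) / 2.0
    np.fill_diagonal(noise, 0.0)
    perturbed = np.clip(target + noise, -0.99, 0.99)
    np.fill_diagonal(perturbed, 1.0)
    return nearest_psd(perturbed)


def _ar1_series(rng: np.random.Generator, n_volumes: int, n_cols: int, phi: float) -> np.ndarray:
    """Unit-variance stationary AR(1) columns."""
    from scipy.signal import lfilter

    e = rng.standard_normal((n_volumes + 50, n_cols))
    z = lfilter([1.0], [1.0, -phi], e, axis=0)[50:]
    return z * np.sqrt(1.0 - phi * phi)


def _cholesky(target: np.ndarray) -> np.ndarray:
    try:
        return np.linalg.cholesky(target + 1e-10 * np.eye(target.shape[0]))
    except np.linalg.LinAlgError as exc:  # pragma: no cover - guarded by nearest_psd
        raise np.linalg.LinAlgError(
            "Cholesky factorization failed after PSD projection"
        ) from exc


def simulate_subject(
    spec: SimulationSpec,
    subject_idx: int,
    condition: str,
    targets: dict[str, np.ndarray] | None = None,
) -> tuple[SubjectTimeseries, MotionTrace, dict[str, np.ndarray]]:
    """Simulate one subject x condition scan.

    Returns the raw (nuisance-contaminated) time series, the motion trace, and
    the nuisance proxy series ({"wm": ..., "csf": ...}). With ``dynamic_only``
    the condition effect is applied only to the volumes that survive the
    initial discard and fall in the first analysis window
    (rows ``n_discard .. n_discard + effect_window - 1``).
    """
    if targets is None:
        targets = build_condition_targets(spec)
    if condition not in targets:
        raise KeyError(f"unknown condition {condition!r}")
    cond_idx = spec.conditions.index(condition)
    rng = _subject_condition_rng(spec, subject_idx, cond_idx)
    T, N = spec.n_volumes, spec.n_rois

    target = _subject_target(spec, targets[condition], subject_idx)
    z = _ar1_series(rng, T, N, spec.ar_coefficient)

    if (
        spec.dynamic_only
        and condition == spec.effect_condition
        and spec.effect_scale < 1.0
    ):
        base_target = _subject_target(spec, targets[spec.conditions[0]], subject_idx)
        L_eff = _cholesky(target)
        L_base = _cholesky(base_target)
        lo = spec.n_discard_volumes
        hi = min(T, lo + spec.effect_window_volumes)
        signal = z @ L_base.T
        signal[lo:hi] = z[lo:hi] @ L_eff.T
    else:
        signal = z @ _cholesky(target).T

    # nuisance contamination, removed later by the preprocessing stage
    trend = np.linspace(-1.0, 1.0, T)
    steps = np.column_stack(
        [
            rng.normal(0.0, 0.01, size=(T, 3)),  # translations, mm
            rng.normal(0.0, 2e-4, size=(T, 3)),  # rotations, radians
        ]
    )
    motion = np.cumsum(steps, axis=0)
    wm = _ar1_series(rng, T, 1, spec.ar_coefficient).ravel()
    csf = _ar1_series(rng, T, 1, spec.ar_coefficient).ravel()

    trend_load = rng.normal(0.0, spec.trend_loading, size=N)
    motion_load = rng.normal(0.0, spec.motion_loading, size=(6, N))
    wm_load = rng.normal(0.0, spec.wm_loading, size=N)
    csf_load = rng.normal(0.0, spec.csf_loading, size=N)

    data = (
        signal
        + np.outer(trend, trend_load)
        + motion @ motion_load
        + np.outer(wm, wm_load)
        + np.outer(csf, csf_load)
    )

    subject_id = spec.subject_ids()[subject_idx]
    ts = SubjectTimeseries(
        data=data,
        tr_seconds=spec.tr_seconds,
        subject_id=subject_id,
        condition=condition,
        stage="raw",
        roi_labels=roi_labels(spec),
    )
    trace = MotionTrace(params=motion, subject_id=subject_id, condition=condition)
    return ts, trace, {"wm": wm, "csf": csf}


def roi_labels(spec: SimulationSpec) -> list[str]:
    labels = [f"ROI{k + 1:03d}" for k in range(spec.n_rois)]
    labels[spec.hub_index] = "Supp_Motor_Area_L"
    return labels


def _atlas_table(spec: SimulationSpec) -> list[tuple[int, str, float, float, float, str]]:
    rng = np.random.default_rng(np.random.SeedSequence(entropy=spec.seed, spawn_key=(999,)))
    coords = np.round(rng.uniform(-70, 70, size=(spec.n_rois, 3)), 1)
    comm = roi_communities(spec)
    labels = roi_labels(spec)
    return [
        (k + 1, labels[k], *coords[k], f"community_{comm[k] + 1}")
        for k in range(spec.n_rois)
    ]


def simulate_study(spec: SimulationSpec, out_dir: str | Path, force: bool = False) -> Path:
    """Write a full synthetic study to ``out_dir``.

    Emits the ROI atlas, one time-series TSV, one SPM-style motion file and one
    nuisance TSV per subject x condition, plus a manifest recording the spec.
    With ``plant_motion_outlier`` the last subject's last condition receives a
    1.2 mm translation spike so the QC stage has something to exclude.
    Deterministic: rerunning with the same spec reproduces every byte.
    """
    from .io_core import RoiAtlas, write_roi_atlas

    out = Path(out_dir)
    if out.exists() and any(out.iterdir()) and not force:
        raise FileExistsError(f"output directory {out} is not empty (use force)")
    out.mkdir(parents=True, exist_ok=True)

    atlas = RoiAtlas.from_rows(_atlas_table(spec))
    write_roi_atlas(out / "atlas.tsv", atlas)

    targets = build_condition_targets(spec)
    labels = roi_labels(spec)
    for s_idx, sid in enumerate(spec.subject_ids()):
        for condition in spec.conditions:
            ts, trace, nuis = simulate_subject(spec, s_idx, condition, targets)
            if (
                spec.plant_motion_outlier
                and s_idx == spec.n_subjects - 1
                and condition == spec.conditions[-1]
            ):
                trace.params[spec.n_volumes // 2, 0] += 1.2
            stem = f"{sid}_cond-{condition}"
            _write_tsv(out / f"{stem}_ts.tsv", ts.data, labels)
            np.savetxt(out / f"{stem}_motion.txt", trace.params, fmt="%.8e")
            _write_tsv(
                out / f"{stem}_nuisance.tsv",
                np.column_stack([nuis["wm"], nuis["csf"]]),
                ["wm", "csf"],
            )

    manifest = {
        "generator": "postrest.synthetic_data",
        "spec": _spec_to_jsonable(spec),
        "conditions": list(spec.conditions),
        "subjects": spec.subject_ids(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return out


def simulate_clean_stacks(
    spec: SimulationSpec,
    band_lo: float = 0.01,
    band_hi: float = 0.08,
    return_cleaned: bool = False,
):
    """Simulate a study in memory and push it through preprocessing.

    Convenience for replicate-based experiments: returns the per-condition
    connectivity stacks (and optionally the cleaned series) without touching
    disk. Applies the standard chain: volume discard, nuisance regression
    (trend + motion + WM/CSF), band-pass.
    """
    from .connectivity import assemble_condition_stacks, pearson_matrix
    from .preprocess import (
        bandpass,
        build_confound_matrix,
        discard_initial_volumes,
        regress_nuisance,
    )

    targets = build_condition_targets(spec)
    cleaned = {}
    for s_idx, sid in enumerate(spec.subject_ids()):
        for cond in spec.conditions:
            ts, trace, nuis = simulate_subject(spec, s_idx, cond, targets)
            ts = discard_initial_volumes(ts, spec.n_discard_volumes)
            nd = spec.n_discard_volumes
            X, names = build_confound_matrix(
                ts.n_volumes,
                motion=trace.params[nd:],
                wm=nuis["wm"][nd:],
                csf=nuis["csf"][nd:],
            )
            ts = regress_nuisance(ts, X, names)
            cleaned[(sid, cond)] = bandpass(ts, band_lo, band_hi)
    mats = {key: pearson_matrix(ts) for key, ts in cleaned.items()}
    stacks = assemble_condition_stacks(
        mats, list(spec.conditions), spec.subject_ids()
    )
    if return_cleaned:
        return stacks, cleaned
    return stacks


def spec_from_manifest(path: str | Path) -> SimulationSpec:
    """Rebuild the SimulationSpec recorded in a study manifest."""
    manifest = json.loads(Path(path).read_text())
    raw = dict(manifest["spec"])
    raw["conditions"] = tuple(raw["conditions"])
    raw["hub_neighbors"] = tuple(raw["hub_neighbors"])
    raw["effect_edges"] = tuple(tuple(e) for e in raw["effect_edges"])
    return SimulationSpec(**raw)


def _spec_to_jsonable(spec: SimulationSpec) -> dict:
    d = asdict(spec)
    d["conditions"] = list(spec.conditions)
    d["hub_neighbors"] = list(spec.hub_neighbors)
    d["effect_edges"] = [list(e) for e in spec.effect_edges]
    return d


def _write_tsv(path: Path, data: np.ndarray, header: list[str]) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in np.atleast_2d(data):
            fh.write("\t".join(f"{v:.8e}" for v in row) + "\n")
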
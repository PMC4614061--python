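"""File formats, configuration, logging, and pipeline orchestration.

All on-disk formats are plain text: TSV time series (volumes x ROIs with a
header of ROI labels), TSV square matrices with shared row/column headers, a
TSV ROI atlas, SPM ``rp_*.txt``-style whitespace motion files, YAML
configuration, and TSV result tables. ROI indices are 1-based in every file
and 0-based in memory; the atlas is the single source of ROI order, and
readers re-order permuted columns by label.

``run_pipeline`` chains the stages in analysis order — QC, preprocessing,
connectivity, NBS, graph construction, nodal metrics and statistics, dynamic
intervals, connectivity pattern — and is a pure function of
(input files, config, seed): a rerun reproduces every stochastic output
bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .preprocess import (
    MotionTrace,
    SubjectTimeseries,
    bandpass,
    build_confound_matrix,
    discard_initial_volumes,
    motion_qc,
    regress_nuisance,
)

logger = logging.getLogger("postrest")

__all__ = [
    "RoiAtlas",
    "StudyConfig",
    "StudyBundle",
    "read_roi_atlas",
    "write_roi_atlas",
    "read_timeseries",
    "read_motion_params",
    "read_matrix",
    "write_matrix",
    "load_config",
    "load_study_bundle",
    "run_pipeline",
    "PIPELINE_STAGES",
]


# ---------------------------------------------------------------------------
# domain types

@dataclass
class RoiAtlas:
    """Ordered ROI table: 1-based index, unique label, MNI coordinates, class."""

    indices: list[int]
    labels: list[str]
    coords: np.ndarray  # (N, 3) millimeters
    region_classes: list[str]

    def __post_init__(self) -> None:
        n = len(self.labels)
        if n < 2:
            raise ValueError("atlas needs at least 2 ROIs")
        if self.indices != list(range(1, n + 1)):
            raise ValueError("atlas indices must be consecutive 1..N")
        if len(set(self.labels)) != n:
            dupes = sorted({l for l in self.labels if self.labels.count(l) > 1})
            raise ValueError(f"duplicate ROI labels: {dupes}")
        self.coords = np.asarray(self.coords, dtype=float).reshape(n, 3)

    @classmethod
    def from_rows(cls, rows) -> "RoiAtlas":
        idx, labels, xs, ys, zs, classes = zip(*rows)
        return cls(
            indices=list(idx),
            labels=list(labels),
            coords=np.column_stack([xs, ys, zs]),
            region_classes=list(classes),
        )

    @property
    def n_rois(self) -> int:
        return len(self.labels)


_CONFIG_DEFAULTS: dict = {
    "tr_seconds": 2.61,
    "n_discard_volumes": 10,
    "band_lo_hz": 0.01,
    "band_hi_hz": 0.08,
    "max_translation_mm": 1.0,
    "max_rotation_deg": 1.0,
    "sparsity_grid": [0.12, 0.14, 0.16, 0.18, 0.20, 0.22, 0.24, 0.26, 0.28],
    "nbs_thresholds": [3.2, 3.3, 3.4, 3.6, 3.8, 4.0],
    "n_permutations": 5000,
    "alpha_nbs": 0.0125,
    "alpha_nodal": 0.05,
    "n_intervals": 3,
    "dynamic_sparsity": 0.18,
    "consistency_min_subjects": 13,
    "conditions": ["baseline", "secure", "dismissing", "preoccupied"],
    "baseline_condition": "baseline",
    "focal_node": 0,
    "posthoc_test": "wilcoxon_signed_rank",
    "omnibus_test": "friedman",
    "heavy_metrics": True,
    "seed": 0,
}


@dataclass
class StudyConfig:
    """Validated analysis configuration with study-design defaults.

    Defaults encode the reference design: TR 2.61 s, 10 discard volumes,
    0.01-0.08 Hz band, sparsity grid 12-28% in steps of 2%, 5000 NBS
    permutations at alpha 0.0125 (0.05 Bonferroni-divided by the four primary
    contrast families), 3 dynamic intervals at 18% sparsity, and an edge
    consistency cut of 13 subjects.
    """

    tr_seconds: float = _CONFIG_DEFAULTS["tr_seconds"]
    n_discard_volumes: int = _CONFIG_DEFAULTS["n_discard_volumes"]
    band_lo_hz: float = _CONFIG_DEFAULTS["band_lo_hz"]
    band_hi_hz: float = _CONFIG_DEFAULTS["band_hi_hz"]
    max_translation_mm: float = _CONFIG_DEFAULTS["max_translation_mm"]
    max_rotation_deg: float = _CONFIG_DEFAULTS["max_rotation_deg"]
    sparsity_grid: list[float] = field(
        default_factory=lambda: list(_CONFIG_DEFAULTS["sparsity_grid"])
    )
    nbs_thresholds: list[float] = field(
        default_factory=lambda: list(_CONFIG_DEFAULTS["nbs_thresholds"])
    )
    n_permutations: int = _CONFIG_DEFAULTS["n_permutations"]
    alpha_nbs: float = _CONFIG_DEFAULTS["alpha_nbs"]
    alpha_nodal: float = _CONFIG_DEFAULTS["alpha_nodal"]
    n_intervals: int = _CONFIG_DEFAULTS["n_intervals"]
    dynamic_sparsity: float = _CONFIG_DEFAULTS["dynamic_sparsity"]
    consistency_min_subjects: int = _CONFIG_DEFAULTS["consistency_min_subjects"]
    conditions: list[str] = field(
        default_factory=lambda: list(_CONFIG_DEFAULTS["conditions"])
    )
    baseline_condition: str = _CONFIG_DEFAULTS["baseline_condition"]
    focal_node: int = _CONFIG_DEFAULTS["focal_node"]
    posthoc_test: str = _CONFIG_DEFAULTS["posthoc_test"]
    omnibus_test: str = _CONFIG_DEFAULTS["omnibus_test"]
    heavy_metrics: bool = _CONFIG_DEFAULTS["heavy_metrics"]
    seed: int = _CONFIG_DEFAULTS["seed"]

    def __post_init__(self) -> None:
        nyquist = 1.0 / (2.0 * self.tr_seconds)
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds: must be positive")
        if self.n_discard_volumes < 0:
            raise ValueError("n_discard_volumes: must be >= 0")
        if not 0 <= self.band_lo_hz < self.band_hi_hz:
            raise ValueError("band_lo_hz/band_hi_hz: need 0 <= lo < hi")
        if self.band_hi_hz >= nyquist:
            raise ValueError(
                f"band_hi_hz: {self.band_hi_hz} Hz not below Nyquist "
                f"{nyquist:.4f} Hz for tr_seconds {self.tr_seconds}"
            )
        grid = list(self.sparsity_grid)
        if any(not 0 < s <= 1 for s in grid):
            raise ValueError("sparsity_grid: fractions must lie in (0, 1]")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("sparsity_grid: must be strictly increasing")
        if self.n_permutations < 1:
            raise ValueError("n_permutations: must be >= 1")
        if self.baseline_condition not in self.conditions:
            raise ValueError("baseline_condition: not among conditions")
        if len(self.conditions) != len(set(self.conditions)):
            raise ValueError("conditions: labels must be unique")
        if self.n_intervals < 1:
            raise ValueError("n_intervals: must be >= 1")
        if not 0 < self.dynamic_sparsity <= 1:
            raise ValueError("dynamic_sparsity: must lie in (0, 1]")

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class StudyBundle:
    """Everything one study run needs, loaded into memory."""

    atlas: RoiAtlas
    subjects: list[str]
    conditions: list[str]
    timeseries: dict[tuple[str, str], SubjectTimeseries]
    motion: dict[tuple[str, str], MotionTrace]
    nuisance: dict[tuple[str, str], pd.DataFrame]
    config: StudyConfig

    def __post_init__(self) -> None:
        shapes = set()
        for sid in self.subjects:
            for cond in self.conditions:
                key = (sid, cond)
                if key not in self.timeseries:
                    raise ValueError(
                        f"subject {sid!r} is missing condition {cond!r}"
                    )
                shapes.add(self.timeseries[key].data.shape)
        if len(shapes) > 1:
            raise ValueError(f"inconsistent time-series shapes: {sorted(shapes)}")


# ---------------------------------------------------------------------------
# readers / writers

def read_roi_atlas(path: str | Path) -> RoiAtlas:
    """Parse a TSV atlas with columns index, label, x, y, z, class."""
    path = Path(path)
    rows = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["index", "label", "x", "y", "z", "class"]
        if [h.strip().lower() for h in header] != expected:
            raise ValueError(
                f"{path}: expected header {expected}, got {header}"
            )
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}:{lineno}: expected 6 fields, got {len(parts)}")
            try:
                rows.append(
                    (
                        int(parts[0]),
                        parts[1],
                        float(parts[2]),
                        float(parts[3]),
                        float(parts[4]),
                        parts[5],
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed row ({exc})") from None
    return RoiAtlas.from_rows(rows)


def write_roi_atlas(path: str | Path, atlas: RoiAtlas) -> None:
    with open(path, "w") as fh:
        fh.write("index\tlabel\tx\ty\tz\tclass\n")
        for k in range(atlas.n_rois):
            x, y, z = atlas.coords[k]
            fh.write(
                f"{atlas.indices[k]}\t{atlas.labels[k]}\t{x:g}\t{y:g}\t{z:g}\t"
                f"{atlas.region_classes[k]}\n"
            )


def read_timeseries(
    path: str | Path,
    atlas: RoiAtlas,
    tr_seconds: float,
    subject_id: str = "",
    condition: str = "",
) -> SubjectTimeseries:
    """Read a volumes x ROIs TSV; columns are matched to atlas order by label."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t")
    file_labels = list(frame.columns)
    if set(file_labels) != set(atlas.labels):
        missing = sorted(set(atlas.labels) - set(file_labels))
        extra = sorted(set(file_labels) - set(atlas.labels))
        raise ValueError(
            f"{path}: ROI labels do not match atlas "
            f"(missing: {missing[:5]}, unexpected: {extra[:5]})"
        )
    data = frame[atlas.labels].to_numpy(dtype=float)
    if np.isnan(data).any():
        bad = int(np.argwhere(np.isnan(data))[0][0]) + 2
        raise ValueError(f"{path}: NaN value near line {bad}")
    return SubjectTimeseries(
        data=data,
        tr_seconds=tr_seconds,
        subject_id=subject_id,
        condition=condition,
        roi_labels=list(atlas.labels),
    )


def read_motion_params(
    path: str | Path, subject_id: str = "", condition: str = ""
) -> MotionTrace:
    """Read an SPM rp-style whitespace file: 3 translations mm, 3 rotations rad."""
    arr = np.loadtxt(path, ndmin=2)
    if arr.shape[1] != 6:
        raise ValueError(
            f"{path}: motion file must have 6 columns, found {arr.shape[1]}"
        )
    return MotionTrace(params=arr, subject_id=subject_id, condition=condition)


def read_matrix(path: str | Path, symmetric: bool = True) -> tuple[np.ndarray, list[str]]:
    """Read a square TSV matrix with a shared row/column header."""
    path = Path(path)
    frame = pd.read_csv(path, sep="\t", index_col=0)
    labels = list(frame.columns)
    if list(frame.index) != labels:
        raise ValueError(f"{path}: row and column headers differ")
    M = frame.to_numpy(dtype=float)
    if M.shape[0] != M.shape[1]:
        raise ValueError(f"{path}: matrix is not square: {M.shape}")
    if symmetric and not np.allclose(M, M.T, atol=1e-10):
        raise ValueError(f"{path}: matrix is asymmetric beyond 1e-10")
    return M, labels


def write_matrix(path: str | Path, matrix: np.ndarray, labels: list[str]) -> None:
    M = np.asarray(matrix, dtype=float)
    if M.shape != (len(labels), len(labels)):
        raise ValueError("label count must match matrix size")
    with open(path, "w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for k, lbl in enumerate(labels):
            fh.write(lbl + "\t" + "\t".join(f"{v:.17g}" for v in M[k]) + "\n")


def load_config(path: str | Path | None = None, **overrides) -> StudyConfig:
    """Load a YAML config; unknown keys are rejected, all defaults documented
    on :class:`StudyConfig`. An empty (or absent) file yields pure defaults.
    """
    values: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"{path}: config must be a mapping of keys to values")
        values.update(raw)
    values.update(overrides)
    unknown = sorted(set(values) - set(_CONFIG_DEFAULTS))
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    return StudyConfig(**values)


def load_study_bundle(data_dir: str | Path, config: StudyConfig) -> StudyBundle:
    """Load a study directory (atlas + per subject x condition files).

    The directory layout is the one ``simulate_study`` writes:
    ``atlas.tsv``, ``manifest.json`` and
    ``<subject>_cond-<condition>_{ts.tsv,motion.txt,nuisance.tsv}``.
    """
    data_dir = Path(data_dir)
    atlas = read_roi_atlas(data_dir / "atlas.tsv")
    manifest = json.loads((data_dir / "manifest.json").read_text())
    subjects = manifest["subjects"]
    conditions = manifest["conditions"]
    if set(conditions) != set(config.conditions):
        raise ValueError(
            f"study conditions {conditions} do not match config "
            f"{config.conditions}"
        )
    timeseries, motion, nuisance = {}, {}, {}
    for sid in subjects:
        for cond in config.conditions:
            stem = data_dir / f"{sid}_cond-{cond}"
            ts_path = Path(f"{stem}_ts.tsv")
            if not ts_path.exists():
                raise FileNotFoundError(
                    f"subject {sid!r} is missing condition {cond!r}: {ts_path}"
                )
            timeseries[(sid, cond)] = read_timeseries(
                ts_path, atlas, config.tr_seconds, sid, cond
            )
            motion[(sid, cond)] = read_motion_params(
                f"{stem}_motion.txt", sid, cond
            )
            nuisance[(sid, cond)] = pd.read_csv(f"{stem}_nuisance.tsv", sep="\t")
    return StudyBundle(
        atlas=atlas,
        subjects=list(subjects),
        conditions=list(config.conditions),
        timeseries=timeseries,
        motion=motion,
        nuisance=nuisance,
        config=config,
    )


# ---------------------------------------------------------------------------
# pipeline

PIPELINE_STAGES = [
    "qc",
    "preprocess",
    "connect",
    "nbs",
    "graphs",
    "metrics",
    "dynamic",
    "pattern",
]


def _setup_run_logging(out_dir: Path, verbose: bool = False) -> None:
    logger.setLevel(logging.DEBUG)
    logger.handlers = [h for h in logger.handlers if not isinstance(h, logging.FileHandler)]
    if not any(isinstance(h, logging.StreamHandler) for h in logger.handlers):
        sh = logging.StreamHandler()
        sh.setLevel(logging.INFO if verbose else logging.WARNING)
        sh.setFormatter(logging.Formatter("[%(levelname)s] %(name)s: %(message)s"))
        logger.addHandler(sh)
    fh = logging.FileHandler(out_dir / "run.log", mode="w")
    fh.setLevel(logging.DEBUG)
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(fh)


def run_pipeline(
    config: StudyConfig,
    data_dir: str | Path,
    out_dir: str | Path,
    stages: list[str] | None = None,
    verbose: bool = False,
) -> dict:
    """Execute the analysis pipeline and write result tables to ``out_dir``.

    ``stages`` selects which stages' outputs to write; prerequisite
    computations always run in memory in the fixed order of
    ``PIPELINE_STAGES``. Returns a results dictionary with the in-memory
    objects of every executed stage. Fails before any computation if a subject
    is missing a condition.
    """
    from .connectivity import assemble_condition_stacks, pearson_matrix
    from .dynamic_analysis import (
        baseline_normalize,
        interval_condition_tests,
        interval_metrics,
    )
    from .graph_build import build_graph_ensemble, sparsify_grid
    from .group_stats import omnibus_condition_test, pairwise_posthoc
    from .nbs import nbs_contrast_battery
    from .nodal_metrics import metric_auc, nodal_metrics_table, METRIC_COLUMNS
    from .pattern_analysis import consistent_neighbors, edge_consistency

    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_run_logging(out, verbose)
    requested = list(PIPELINE_STAGES) if stages is None else list(stages)
    bad = sorted(set(requested) - set(PIPELINE_STAGES))
    if bad:
        raise ValueError(f"unknown pipeline stages: {bad}")
    last = max(PIPELINE_STAGES.index(s) for s in requested)
    run_stages = PIPELINE_STAGES[: last + 1]
    results: dict = {"config": config}
    stage_times: dict[str, float] = {}
    logger.info("pipeline start: stages=%s seed=%d", requested, config.seed)

    bundle = load_study_bundle(data_dir, config)
    results["bundle"] = bundle

    def _write(name: str, frame: pd.DataFrame) -> None:
        frame.to_csv(out / name, sep="\t", index=False)

    current = "qc"
    try:
        # --- qc ------------------------------------------------------------
        t_stage = time.time()
        qc_rows = []
        excluded: set[str] = set()
        for sid in bundle.subjects:
            for cond in bundle.conditions:
                rep = motion_qc(
                    bundle.motion[(sid, cond)],
                    config.max_translation_mm,
                    config.max_rotation_deg,
                )
                qc_rows.append(
                    {
                        "subject": sid,
                        "condition": cond,
                        "max_translation_mm": rep.max_translation_mm,
                        "max_rotation_deg": rep.max_rotation_deg,
                        "passed": rep.passed,
                    }
                )
                if not rep.passed:
                    excluded.add(sid)
        included = [s for s in bundle.subjects if s not in excluded]
        qc_table = pd.DataFrame(qc_rows)
        qc_table["subject_included"] = ~qc_table["subject"].isin(excluded)
        results["qc"] = qc_table
        results["included_subjects"] = included
        if len(included) < 3:
            raise ValueError("fewer than 3 subjects pass motion QC")
        if "qc" in requested:
            _write("qc_report.tsv", qc_table)
        logger.info("qc: %d/%d subjects included", len(included), len(bundle.subjects))
        stage_times["qc"] = time.time() - t_stage

        # --- preprocess ----------------------------------------------------
        current = "preprocess"
        t_stage = time.time()
        cleaned: dict[tuple[str, str], SubjectTimeseries] = {}
        if PIPELINE_STAGES.index("preprocess") <= last:
            for sid in included:
                for cond in bundle.conditions:
                    key = (sid, cond)
                    ts = discard_initial_volumes(
                        bundle.timeseries[key], config.n_discard_volumes
                    )
                    nuis = bundle.nuisance[key]
                    motion_params = bundle.motion[key].params[
                        config.n_discard_volumes :
                    ]
                    X, names = build_confound_matrix(
                        ts.n_volumes,
                        motion=motion_params,
                        wm=nuis["wm"].to_numpy()[config.n_discard_volumes :],
                        csf=nuis["csf"].to_numpy()[config.n_discard_volumes :],
                    )
                    ts = regress_nuisance(ts, X, names)
                    cleaned[key] = bandpass(ts, config.band_lo_hz, config.band_hi_hz)
            results["cleaned"] = cleaned
            if "preprocess" in requested:
                for (sid, cond), ts in cleaned.items():
                    pd.DataFrame(ts.data, columns=bundle.atlas.labels).to_csv(
                        out / f"{sid}_cond-{cond}_cleaned.tsv", sep="\t", index=False
                    )
            stage_times["preprocess"] = time.time() - t_stage

        # --- connect -------------------------------------------------------
        if PIPELINE_STAGES.index("connect") <= last:
            current = "connect"
            t_stage = time.time()
            matrices = {key: pearson_matrix(ts) for key, ts in cleaned.items()}
            stacks = assemble_condition_stacks(
                matrices, bundle.conditions, included
            )
            results["stacks"] = stacks
            if "connect" in requested:
                for (sid, cond), mat in matrices.items():
                    write_matrix(
                        out / f"{sid}_cond-{cond}_fc.tsv",
                        mat.values,
                        bundle.atlas.labels,
                    )
            stage_times["connect"] = time.time() - t_stage

        # --- nbs -----------------------------------------------------------
        if PIPELINE_STAGES.index("nbs") <= last:
            current = "nbs"
            t_stage = time.time()
            nbs_table, nbs_components = nbs_contrast_battery(
                stacks,
                config.nbs_thresholds,
                baseline=config.baseline_condition,
                n_permutations=config.n_permutations,
                alpha=config.alpha_nbs,
                seed=config.seed,
            )
            results["nbs"] = nbs_table
            results["nbs_components"] = nbs_components
            logger.info(
                "nbs: %d contrasts x %d thresholds, %d permutations (seed %d)",
                nbs_table["contrast"].nunique(),
                len(config.nbs_thresholds),
                config.n_permutations,
                config.seed,
            )
            if "nbs" in requested:
                _write("nbs_results.tsv", nbs_table)
                edge_rows = []
                for (label, tau), comp in nbs_components.items():
                    if comp is None:
                        continue
                    for i, j in comp.edges:
                        edge_rows.append(
                            {
                                "contrast": label,
                                "tau": tau,
                                "node_i": bundle.atlas.labels[i],
                                "node_j": bundle.atlas.labels[j],
                            }
                        )
                _write("nbs_component_edges.tsv", pd.DataFrame(edge_rows))
            stage_times["nbs"] = time.time() - t_stage

        # --- graphs ----------------------------------------------------------
        if PIPELINE_STAGES.index("graphs") <= last:
            current = "graphs"
            t_stage = time.time()
            ensemble = build_graph_ensemble(stacks, config.sparsity_grid)
            results["ensemble"] = ensemble
            if "graphs" in requested:
                dens_rows = [
                    {
                        "subject": sid,
                        "condition": cond,
                        "target_density": dens,
                        "n_edges": g.n_edges,
                        "achieved_density": g.achieved_density,
                        "bridge_forced": g.bridge_forced,
                    }
                    for (sid, cond, dens), g in sorted(ensemble.items())
                ]
                _write("graph_densities.tsv", pd.DataFrame(dens_rows))
            stage_times["graphs"] = time.time() - t_stage

        # --- metrics ---------------------------------------------------------
        if PIPELINE_STAGES.index("metrics") <= last:
            current = "metrics"
            t_stage = time.time()
            metrics_table = nodal_metrics_table(
                ensemble, seed=config.seed, heavy=config.heavy_metrics
            )
            results["metrics"] = metrics_table
            value_cols = [
                c for c in METRIC_COLUMNS if c in metrics_table.columns
            ]
            auc_rows = []
            grid = np.asarray(config.sparsity_grid)
            for (sid, cond, node), chunk in metrics_table.groupby(
                ["subject", "condition", "node"], sort=True
            ):
                chunk = chunk.sort_values("sparsity")
                row = {"subject": sid, "condition": cond, "node": node}
                for c in value_cols:
                    row[f"{c}_auc"] = float(
                        metric_auc(grid, chunk[c].to_numpy())
                    )
                auc_rows.append(row)
            auc_table = pd.DataFrame(auc_rows)
            results["metric_auc"] = auc_table
            omnibus = omnibus_condition_test(
                metrics_table, kind=config.omnibus_test, metrics=value_cols
            )
            results["omnibus"] = omnibus
            posthoc = pairwise_posthoc(
                metrics_table,
                kind=config.posthoc_test,
                correction="fdr_bh",
                alpha=config.alpha_nodal,
                metrics=value_cols,
            )
            results["posthoc"] = posthoc
            if "metrics" in requested:
                _write("nodal_metrics.tsv", metrics_table)
                _write("metric_auc.tsv", auc_table)
                _write("omnibus_tests.tsv", omnibus)
                _write("posthoc_tests.tsv", posthoc)
            stage_times["metrics"] = time.time() - t_stage

        # --- dynamic ---------------------------------------------------------
        if PIPELINE_STAGES.index("dynamic") <= last:
            current = "dynamic"
            t_stage = time.time()
            itable = interval_metrics(
                cleaned,
                n_intervals=config.n_intervals,
                sparsity=config.dynamic_sparsity,
            )
            normalized = baseline_normalize(itable, config.baseline_condition)
            dyn_tests = interval_condition_tests(
                normalized,
                node=config.focal_node,
                baseline=config.baseline_condition,
                alpha=config.alpha_nodal,
            )
            results["dynamic_metrics"] = normalized
            results["dynamic_tests"] = dyn_tests
            if "dynamic" in requested:
                _write("dynamic_metrics.tsv", normalized)
                _write("dynamic_tests.tsv", dyn_tests)
            stage_times["dynamic"] = time.time() - t_stage

        # --- pattern ---------------------------------------------------------
        if PIPELINE_STAGES.index("pattern") <= last:
            current = "pattern"
            t_stage = time.time()
            pattern_graphs = {
                (sid, cond): g
                for (sid, cond, dens), g in ensemble.items()
                if abs(dens - config.dynamic_sparsity) < 1e-12
            }
            if not pattern_graphs:
                grid18 = {}
                for cond, stack in stacks.items():
                    for sid, mat in zip(stack.subject_ids, stack.matrices):
                        grid18[(sid, cond)] = sparsify_grid(
                            mat.values, [config.dynamic_sparsity]
                        )[config.dynamic_sparsity]
                pattern_graphs = grid18
            profile = edge_consistency(
                pattern_graphs, config.focal_node, config.dynamic_sparsity
            )
            results["consistency_profile"] = profile
            neighbor_rows = []
            for cond in bundle.conditions:
                nbs_set = consistent_neighbors(
                    profile, cond, config.consistency_min_subjects
                )
                neighbor_rows.append(
                    {
                        "condition": cond,
                        "n_consistent_neighbors": len(nbs_set),
                        "neighbors": ",".join(
                            bundle.atlas.labels[k] for k in sorted(nbs_set)
                        ),
                    }
                )
            results["consistent_neighbors"] = pd.DataFrame(neighbor_rows)
            if "pattern" in requested:
                prof = profile.table.copy()
                prof["partner_label"] = [
                    bundle.atlas.labels[k] for k in prof["partner"]
                ]
                _write("consistency_profile.tsv", prof)
                _write("consistent_neighbors.tsv", results["consistent_neighbors"])
            stage_times["pattern"] = time.time() - t_stage
    except Exception:
        logger.exception("pipeline stage %r failed", current)
        (out / "INCOMPLETE").write_text(
            f"pipeline aborted during stage: {current}\n"
        )
        raise RuntimeError(f"pipeline stage {current!r} failed") from None

    (out / "INCOMPLETE").unlink(missing_ok=True)
    run_log = {
        "config": asdict(config),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": requested,
        "stage_seconds": {k: round(v, 3) for k, v in stage_times.items()},
        "versions": _versions(),
        "elapsed_seconds": round(time.time() - t0, 3),
    }
    (out / "run_log.json").write_text(json.dumps(run_log, indent=2, sort_keys=True))
    logger.info("pipeline done in %.1f s", time.time() - t0)
    return results


def _versions() -> dict[str, str]:
    import importlib.metadata as md

    out = {}
    for pkg in ("postrest", "numpy", "scipy", "pandas", "networkx", "statsmodels"):
        try:
            out[pkg] = md.version(pkg)
        except md.PackageNotFoundError:
            out[pkg] = "unknown"
    return out
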
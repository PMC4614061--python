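"""Synthetic study generator: targets, PSD repair, determinism, consistency."""

import json

import numpy as np
import pytest

from postrest import (
    SimulationSpec,
    build_condition_targets,
    nearest_psd,
    simulate_study,
    simulate_subject,
)
from postrest.synthetic_data import spec_from_manifest


class TestConditionTargets:
    def test_no_effect_means_identical_targets(self, tiny_spec):
        from dataclasses import replace

        spec = replace(tiny_spec, effect_scale=1.0)
        targets = build_condition_targets(spec)
        base = targets["baseline"]
        for cond in spec.conditions:
            assert np.allclose(targets[cond], base)

    def test_effect_edge_scaled_by_delta(self, tiny_spec):
        targets = build_condition_targets(tiny_spec)
        i, j = tiny_spec.effect_edges[0]
        base_val = targets["baseline"][i, j]
        assert base_val == pytest.approx(tiny_spec.rho_hub, abs=0.02)
        assert targets["dismissing"][i, j] == pytest.approx(
            tiny_spec.effect_scale * base_val, abs=0.02
        )

    def test_all_targets_positive_semidefinite(self, tiny_spec):
        for mat in build_condition_targets(tiny_spec).values():
            assert np.linalg.eigvalsh(mat).min() >= -1e-10
            assert np.allclose(np.diag(mat), 1.0)


class TestNearestPsd:
    def test_identity_unchanged(self):
        assert np.array_equal(nearest_psd(np.eye(4)), np.eye(4))

    def test_already_psd_unchanged(self):
        M = np.array([[1.0, 0.5], [0.5, 1.0]])
        assert np.array_equal(nearest_psd(M), M)

    def test_indefinite_matrix_repaired(self):
        M = np.array(
            [[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]]
        )
        assert np.linalg.eigvalsh(M).min() < 0  # genuinely indefinite
        fixed = nearest_psd(M)
        assert np.linalg.eigvalsh(fixed).min() >= -1e-12
        assert np.allclose(np.diag(fixed), 1.0)
        # idempotent on its own output
        assert np.allclose(nearest_psd(fixed), fixed)

    def test_asymmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            nearest_psd(np.array([[1.0, 0.2], [0.5, 1.0]]))


class TestSimulateSubject:
    def test_deterministic_in_seed_subject_condition(self, tiny_spec):
        a, trace_a, nuis_a = simulate_subject(tiny_spec, 2, "secure")
        b, trace_b, nuis_b = simulate_subject(tiny_spec, 2, "secure")
        assert np.array_equal(a.data, b.data)
        assert np.array_equal(trace_a.params, trace_b.params)
        assert np.array_equal(nuis_a["wm"], nuis_b["wm"])
        c, _, _ = simulate_subject(tiny_spec, 3, "secure")
        assert not np.array_equal(a.data, c.data)

    def test_large_t_empirical_correlation_matches_target(self):
        spec = SimulationSpec(
            n_rois=20,
            n_subjects=1,
            n_volumes=50_000,
            n_communities=4,
            hub_neighbors=tuple(range(1, 9)),
            subject_jitter=0.0,
            trend_loading=0.0,
            motion_loading=0.0,
            wm_loading=0.0,
            csf_loading=0.0,
            seed=5,
        )
        targets = build_condition_targets(spec)
        ts, _, _ = simulate_subject(spec, 0, "baseline", targets)
        emp = np.corrcoef(ts.data, rowvar=False)
        assert np.max(np.abs(emp - targets["baseline"])) < 0.02

    def test_empirical_error_shrinks_with_t(self):
        """Convergence: max-abs error at 40x the length is clearly smaller."""
        errs = []
        for T in (500, 20_000):
            spec = SimulationSpec(
                n_rois=15,
                n_subjects=1,
                n_volumes=T,
                n_communities=3,
                hub_neighbors=tuple(range(1, 9)),
                subject_jitter=0.0,
                trend_loading=0.0,
                motion_loading=0.0,
                wm_loading=0.0,
                csf_loading=0.0,
                seed=9,
            )
            targets = build_condition_targets(spec)
            ts, _, _ = simulate_subject(spec, 0, "baseline", targets)
            emp = np.corrcoef(ts.data, rowvar=False)
            errs.append(np.max(np.abs(emp - targets["baseline"])))
        assert errs[1] < errs[0] / 2

    def test_dynamic_only_restricts_effect_to_first_window(self):
        spec = SimulationSpec(
            n_rois=20,
            n_subjects=12,
            n_volumes=240,
            n_communities=4,
            hub_neighbors=tuple(range(1, 9)),
            dynamic_only=True,
            subject_jitter=0.0,
            trend_loading=0.0,
            motion_loading=0.0,
            wm_loading=0.0,
            csf_loading=0.0,
            seed=3,
        )
        i, j = spec.effect_edges[0]
        # average the windowed correlation over replicate subjects
        early, late = [], []
        for s in range(12):
            ts, _, _ = simulate_subject(spec, s, "dismissing")
            lo, hi = spec.n_discard_volumes, spec.n_discard_volumes + 76
            early.append(np.corrcoef(ts.data[lo:hi, i], ts.data[lo:hi, j])[0, 1])
            late.append(np.corrcoef(ts.data[hi:, i], ts.data[hi:, j])[0, 1])
        assert np.mean(early) < np.mean(late) - 0.1

    def test_planted_effect_recoverable_on_effect_edges(self, tiny_spec):
        """Mean dismissing correlation on effect edges below baseline's."""
        wins = 0
        reps = 12
        for rep in range(reps):
            from dataclasses import replace

            spec = replace(tiny_spec, seed=1000 + rep)
            targets = build_condition_targets(spec)
            diffs = []
            for s in range(spec.n_subjects):
                ts_b, _, _ = simulate_subject(spec, s, "baseline", targets)
                ts_d, _, _ = simulate_subject(spec, s, "dismissing", targets)
                rb = np.corrcoef(ts_b.data, rowvar=False)
                rd = np.corrcoef(ts_d.data, rowvar=False)
                for i, j in spec.effect_edges:
                    diffs.append(rb[i, j] - rd[i, j])
            if np.mean(diffs) > 0:
                wins += 1
        assert wins >= int(0.95 * reps)


class TestSimulateStudy:
    def test_default_tiny_study_file_count(self, tiny_spec, tiny_study_dir):
        ts_files = sorted(tiny_study_dir.glob("*_ts.tsv"))
        assert len(ts_files) == tiny_spec.n_subjects * 4

    def test_two_subject_study_has_eight_series(self, tmp_path):
        spec = SimulationSpec(
            n_rois=10,
            n_subjects=2,
            n_volumes=40,
            n_communities=2,
            hub_neighbors=tuple(range(1, 9)),
            seed=0,
        )
        simulate_study(spec, tmp_path / "s")
        assert len(list((tmp_path / "s").glob("*_ts.tsv"))) == 8

    def test_manifest_reload_reproduces_bytes(self, tmp_path):
        spec = SimulationSpec(
            n_rois=10,
            n_subjects=2,
            n_volumes=40,
            n_communities=2,
            hub_neighbors=tuple(range(1, 9)),
            seed=77,
        )
        d1 = tmp_path / "one"
        simulate_study(spec, d1)
        spec2 = spec_from_manifest(d1 / "manifest.json")
        d2 = tmp_path / "two"
        simulate_study(spec2, d2)
        for f1 in sorted(d1.iterdir()):
            assert (d2 / f1.name).read_bytes() == f1.read_bytes()

    def test_refuses_nonempty_directory(self, tmp_path):
        spec = SimulationSpec(
            n_rois=10,
            n_subjects=1,
            n_volumes=40,
            n_communities=2,
            hub_neighbors=tuple(range(1, 9)),
        )
        target = tmp_path / "occupied"
        target.mkdir()
        (target / "existing.txt").write_text("x")
        with pytest.raises(FileExistsError):
            simulate_study(spec, target)
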
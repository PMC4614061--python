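"""Interval splitting, per-interval metrics, baseline normalization, tests."""

import numpy as np
import pandas as pd
import pytest

from postrest import (
    SubjectTimeseries,
    baseline_normalize,
    interval_condition_tests,
    interval_metrics,
    split_intervals,
)


def make_ts(T, n=5, seed=0):
    return SubjectTimeseries(
        data=np.random.default_rng(seed).normal(size=(T, n)), tr_seconds=2.61
    )


class TestSplitIntervals:
    def test_230_volumes_give_three_76_volume_intervals(self):
        pieces = split_intervals(make_ts(230), 3)
        assert [p.n_volumes for p in pieces] == [76, 76, 76]

    def test_nine_volumes_three_intervals(self):
        pieces = split_intervals(make_ts(9), 3)
        assert [p.n_volumes for p in pieces] == [3, 3, 3]

    def test_single_interval_is_identity(self):
        ts = make_ts(50)
        (piece,) = split_intervals(ts, 1)
        assert np.array_equal(piece.data, ts.data)

    def test_intervals_contiguous_in_order(self):
        ts = make_ts(230)
        pieces = split_intervals(ts, 3)
        assert np.array_equal(
            np.vstack([p.data for p in pieces]), ts.data[: 3 * 76]
        )

    def test_zero_intervals_rejected(self):
        with pytest.raises(ValueError):
            split_intervals(make_ts(30), 0)


@pytest.fixture(scope="module")
def cleaned_tiny(tmp_path_factory):
    """Cleaned series of the tiny study, via the pipeline preprocess stage."""
    from postrest import SimulationSpec, load_config, run_pipeline, simulate_study

    spec = SimulationSpec(
        n_rois=20,
        n_subjects=6,
        n_volumes=120,
        n_communities=4,
        hub_neighbors=tuple(range(1, 9)),
        seed=21,
    )
    path = tmp_path_factory.mktemp("dynstudy")
    simulate_study(spec, path, force=True)
    cfg = load_config(None, consistency_min_subjects=3)
    res = run_pipeline(cfg, path, path / "out", stages=["preprocess"])
    return res["cleaned"]


class TestIntervalMetrics:
    def test_deterministic(self, cleaned_tiny):
        t1 = interval_metrics(cleaned_tiny, 3, sparsity=0.2)
        t2 = interval_metrics(cleaned_tiny, 3, sparsity=0.2)
        pd.testing.assert_frame_equal(t1, t2)

    def test_interval_metrics_fluctuate_around_full_series_values(self, cleaned_tiny):
        from postrest import degree_and_strength, pearson_matrix, sparsify_preserving_connectivity

        table = interval_metrics(cleaned_tiny, 3, sparsity=0.2)
        key = next(iter(cleaned_tiny))
        full = pearson_matrix(cleaned_tiny[key])
        g = sparsify_preserving_connectivity(full.values, 0.2)
        deg_full, _ = degree_and_strength(g)
        sub = table[(table["subject"] == key[0]) & (table["condition"] == key[1])]
        per_interval = sub.groupby("interval")["degree"].mean()
        # mean degree is pinned by the density, so windows stay close
        assert np.allclose(per_interval, deg_full.mean(), rtol=0.15)

    def test_too_short_interval_rejected(self, cleaned_tiny):
        with pytest.raises(ValueError):
            interval_metrics(cleaned_tiny, 60, sparsity=0.2)


class TestBaselineNormalize:
    def toy_table(self):
        rows = []
        vals = {
            ("baseline", "s1"): 10.0,
            ("baseline", "s2"): 14.0,
            ("secure", "s1"): 11.0,
            ("secure", "s2"): 13.0,
        }
        for (cond, sid), v in vals.items():
            for interval in (1, 2):
                rows.append(
                    {
                        "subject": sid,
                        "condition": cond,
                        "interval": interval,
                        "node": 0,
                        "degree": v + interval,
                        "strength": 2 * v + interval,
                    }
                )
        return pd.DataFrame(rows)

    def test_baseline_group_mean_exactly_zero_per_interval(self):
        out = baseline_normalize(self.toy_table())
        base = out[out["condition"] == "baseline"]
        for _, chunk in base.groupby("interval"):
            assert chunk["degree"].mean() == 0.0
            assert chunk["strength"].mean() == 0.0

    def test_condition_differences_shift_invariant(self):
        t = self.toy_table()
        shifted = t.copy()
        shifted[["degree", "strength"]] += 100.0
        d1 = baseline_normalize(t)
        d2 = baseline_normalize(shifted)
        diff1 = (
            d1[d1["condition"] == "secure"]["degree"].to_numpy()
            - d1[d1["condition"] == "baseline"]["degree"].to_numpy()
        )
        diff2 = (
            d2[d2["condition"] == "secure"]["degree"].to_numpy()
            - d2[d2["condition"] == "baseline"]["degree"].to_numpy()
        )
        assert np.allclose(diff1, diff2)

    def test_two_subject_toy_matches_direct_subtraction(self):
        out = baseline_normalize(self.toy_table())
        # baseline interval-1 group mean of degree is ((10+1)+(14+1))/2 = 13
        row = out.query(
            "condition == 'secure' and subject == 's1' and interval == 1"
        )
        assert row["degree"].iloc[0] == pytest.approx((11 + 1) - 13.0)

    def test_missing_baseline_rejected(self):
        t = self.toy_table()
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(t[t["condition"] != "baseline"])


class TestIntervalConditionTests:
    def normal_table(self, effect=0.0, seed=0, n=12):
        rng = np.random.default_rng(seed)
        rows = []
        for cond in ["baseline", "secure", "dismissing", "preoccupied"]:
            for s in range(n):
                subj_effect = rng.normal(0, 0.5)
                for interval in (1, 2, 3):
                    bump = (
                        -effect if (cond == "dismissing" and interval == 1) else 0.0
                    )
                    val = 10 + subj_effect + rng.normal(0, 0.5) + bump
                    rows.append(
                        {
                            "subject": f"s{s:02d}",
                            "condition": cond,
                            "interval": interval,
                            "node": 0,
                            "degree": val,
                            "strength": 2 * val,
                        }
                    )
        return pd.DataFrame(rows)

    def test_identical_conditions_no_rejections(self):
        table = self.normal_table(effect=0.0, seed=1)
        # make all narrative conditions literally identical per subject
        piv = table.pivot_table(
            index=["subject", "interval", "node"], columns="condition", values="degree"
        )
        for cond in ["secure", "dismissing", "preoccupied"]:
            table.loc[table["condition"] == cond, "degree"] = (
                piv["secure"].loc[
                    list(
                        zip(
                            table.loc[table["condition"] == cond, "subject"],
                            table.loc[table["condition"] == cond, "interval"],
                            table.loc[table["condition"] == cond, "node"],
                        )
                    )
                ].to_numpy()
            )
            table.loc[table["condition"] == cond, "strength"] = 2 * table.loc[
                table["condition"] == cond, "degree"
            ]
        res = interval_condition_tests(table, node=0, metrics=["degree"])
        assert (res["statistic"].abs() < 1e-12).all()
        assert not res["reject"].any()

    def test_fdr_family_size_is_pairs_by_intervals_by_metrics(self):
        res = interval_condition_tests(self.normal_table(seed=2), node=0)
        assert res.attrs["fdr_family_size"] == 3 * 3 * 2
        assert len(res) == 18

    def test_strong_interval1_effect_detected_only_in_interval1(self):
        res = interval_condition_tests(self.normal_table(effect=2.0, seed=3), node=0)
        dis = res[
            (res["condition_a"] == "dismissing") | (res["condition_b"] == "dismissing")
        ]
        assert dis[dis["interval"] == 1]["reject"].all()
        assert not dis[dis["interval"] > 1]["reject"].any()
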
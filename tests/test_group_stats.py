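"""Normality gate, nonparametric omnibus/post hoc tests, FDR and Bonferroni."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import oracles
from postrest import fdr_bh, omnibus_condition_test, pairwise_posthoc, shapiro_gate


def metrics_table(values_by_condition, nodes=1, sparsity=0.18, metric="degree"):
    """Build a long-format table from {condition: (n_subjects,) array}."""
    rows = []
    for cond, vals in values_by_condition.items():
        for s, v in enumerate(vals):
            for node in range(nodes):
                rows.append(
                    {
                        "subject": f"s{s:02d}",
                        "condition": cond,
                        "sparsity": sparsity,
                        "node": node,
                        metric: v if np.isscalar(v) else v[node],
                    }
                )
    return pd.DataFrame(rows)


class TestShapiroGate:
    def test_skewed_sample_flagged_non_normal(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=23) ** 2
            if not shapiro_gate({"g": x})["g"]:
                hits += 1
        assert hits >= 18

    def test_constant_sample_non_normal_by_convention(self):
        assert shapiro_gate({"g": np.full(10, 3.0)})["g"] is False

    def test_normal_sample_passes_at_about_one_minus_alpha(self):
        passes = sum(
            shapiro_gate({"g": np.random.default_rng(seed).normal(size=23)})["g"]
            for seed in range(200)
        )
        # expect ~190; binomial(200, 0.95) range
        assert 180 <= passes <= 200

    def test_tiny_group_rejected(self):
        with pytest.raises(ValueError):
            shapiro_gate({"g": np.array([1.0, 2.0])})


class TestOmnibus:
    def test_identical_conditions_give_p_one(self):
        vals = np.arange(5.0)
        table = metrics_table({c: vals for c in "abcd"})
        for kind in ("friedman", "kruskal"):
            res = omnibus_condition_test(table, kind=kind)
            assert res["p"].iloc[0] == 1.0
            assert res["statistic"].iloc[0] == 0.0

    def test_friedman_toy_matches_hand_rank_computation(self):
        # 4 subjects x 3 conditions, no ties within subjects
        data = {
            "a": np.array([1.0, 2.0, 3.0, 2.0]),
            "b": np.array([5.0, 6.0, 4.0, 5.0]),
            "c": np.array([9.0, 8.0, 7.0, 9.0]),
        }
        # within-subject ranks are always a=1, b=2, c=3 -> rank sums 4, 8, 12
        n, k = 4, 3
        chi2_hand = 12.0 / (n * k * (k + 1)) * (16 + 64 + 144) - 3 * n * (k + 1)
        p_hand = float(stats.chi2.sf(chi2_hand, k - 1))
        res = omnibus_condition_test(metrics_table(data), kind="friedman")
        assert res["statistic"].iloc[0] == pytest.approx(chi2_hand)
        assert res["p"].iloc[0] == pytest.approx(p_hand)

    def test_kruskal_null_distribution_invariant_to_label_permutation(self):
        rng = np.random.default_rng(0)
        vals = rng.normal(size=(4, 8))
        conds = ["a", "b", "c", "d"]
        t1 = metrics_table(dict(zip(conds, vals)))
        t2 = metrics_table(dict(zip(["d", "a", "c", "b"], vals)))
        r1 = omnibus_condition_test(t1, kind="kruskal")
        r2 = omnibus_condition_test(t2, kind="kruskal")
        assert r1["statistic"].iloc[0] == pytest.approx(r2["statistic"].iloc[0])


class TestPosthoc:
    def test_identical_paired_samples_give_p_one(self):
        vals = np.arange(8.0)
        table = metrics_table({"a": vals, "b": vals})
        res = pairwise_posthoc(table, kind="wilcoxon_signed_rank")
        assert res["p"].iloc[0] == 1.0

    def test_bonferroni_over_six_pairs(self):
        rng = np.random.default_rng(1)
        table = metrics_table({c: rng.normal(size=10) for c in "abcd"})
        res = pairwise_posthoc(table, kind="wilcoxon_signed_rank", correction="bonferroni")
        assert len(res) == 6
        # per-pair level alpha/6: corrected p is raw p times 6 (capped)
        assert np.allclose(
            res["p_corrected"], np.minimum(res["p"] * 6, 1.0), atol=1e-12
        )
        assert 0.05 / 6 == pytest.approx(0.008333, abs=1e-6)

    def test_small_n_wilcoxon_matches_exhaustive_sign_enumeration(self):
        rng = np.random.default_rng(2)
        for trial in range(5):
            x = rng.normal(size=9)
            y = rng.normal(size=9)
            table = metrics_table({"a": x, "b": y})
            res = pairwise_posthoc(table, kind="wilcoxon_signed_rank")
            p_exact = oracles.wilcoxon_exact_two_sided(x - y)
            assert res["p"].iloc[0] == pytest.approx(p_exact, abs=1e-10)

    def test_mann_whitney_route_runs(self):
        rng = np.random.default_rng(3)
        table = metrics_table({"a": rng.normal(size=12), "b": rng.normal(1.5, 1, size=12)})
        res = pairwise_posthoc(table, kind="mann_whitney_u")
        assert res["p"].iloc[0] < 0.05


class TestFdrBh:
    def test_single_p_unchanged(self):
        adj, rej = fdr_bh(np.array([0.03]), q=0.05)
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_printed_toy_vector_all_rejected(self):
        p = np.array([0.01, 0.02, 0.03, 0.04])
        adj, rej = fdr_bh(p, q=0.05)
        # largest k with p_(k) <= k q / m is k = 4 -> everything rejected
        assert rej.all()
        assert np.array_equal(rej, oracles.bh_stepup(p, 0.05))

    def test_all_ones_rejects_nothing(self):
        adj, rej = fdr_bh(np.ones(10), q=0.05)
        assert not rej.any()
        assert np.all(adj == 1.0)

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(4)
        for trial in range(10):
            p = rng.uniform(size=25) ** rng.uniform(0.5, 3)
            _, rej = fdr_bh(p, q=0.05)
            assert np.array_equal(rej, oracles.bh_stepup(p, 0.05))

    def test_adjusted_p_monotone_in_rank(self):
        rng = np.random.default_rng(5)
        p = np.sort(rng.uniform(size=20))
        adj, _ = fdr_bh(p)
        assert np.all(np.diff(adj) >= -1e-15)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh(np.array([0.5, 1.2]))

    def test_bonferroni_rejections_subset_of_bh(self):
        rng = np.random.default_rng(6)
        for trial in range(10):
            p = rng.uniform(size=30) ** 2
            _, bh_rej = fdr_bh(p, q=0.05)
            bonf_rej = p < 0.05 / p.size
            assert np.all(bh_rej[bonf_rej])

    @given(
        st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40)
    )
    def test_stepup_rejections_match_definition_on_arbitrary_p(self, p_list):
        p = np.array(p_list)
        _, rej = fdr_bh(p, q=0.05)
        assert np.array_equal(rej, oracles.bh_stepup(p, 0.05))

    def test_false_discovery_proportion_controlled_on_null(self):
        """Average realized FDP over null p-vectors stays at or below q."""
        rng = np.random.default_rng(7)
        fdp = []
        for rep in range(300):
            p = rng.uniform(size=104)  # all nulls
            _, rej = fdr_bh(p, q=0.05)
            fdp.append(rej.any())
        # with all-null p, FDP = 1 whenever anything is rejected;
        # mean should be <= q up to Monte-Carlo noise
        assert np.mean(fdp) <= 0.05 + 0.03
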
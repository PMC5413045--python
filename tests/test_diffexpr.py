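"""Expression statistics: normalization contract, DE calls, BH, clustering, ddCt."""

import numpy as np
import pandas as pd
import pytest

from crownmir.diffexpr import (
    bh_adjust,
    call_de,
    cluster_features,
    contrast_correlation,
    ddct,
    linkage_to_newick,
    normalize_trimmed_mean,
    screen_responsive,
    trimmed_mean,
    venn,
)
from crownmir.syndata import SimConfig, simulate_ct_table, simulate_microarray


class TestNormalize:
    def test_constant_array_scales_to_target(self):
        m = pd.DataFrame({"a": [1000.0] * 100})
        out = normalize_trimmed_mean(m)
        assert np.allclose(out["a"], 2500.0)

    def test_hand_arithmetic_1_to_100(self):
        m = pd.DataFrame({"a": np.arange(1, 101, dtype=float)})
        out = normalize_trimmed_mean(m)
        # ceil(0.02*100)=2 per tail -> mean of 3..98 = 50.5
        assert trimmed_mean(m["a"].values) == pytest.approx(50.5)
        assert np.allclose(out["a"], m["a"] * (2500 / 50.5))

    def test_post_normalization_trimmed_mean_is_target(self):
        rng = np.random.default_rng(0)
        m = pd.DataFrame(2.0 ** rng.normal(10, 1, size=(500, 4)),
                         columns=list("abcd"))
        out = normalize_trimmed_mean(m)
        for col in out:
            assert trimmed_mean(out[col].values) == pytest.approx(2500.0, rel=1e-9)

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        m = pd.DataFrame(2.0 ** rng.normal(10, 1, size=(300, 2)), columns=["a", "b"])
        once = normalize_trimmed_mean(m)
        twice = normalize_trimmed_mean(once)
        assert np.allclose(once.values, twice.values)

    def test_zero_trimmed_mean_raises(self):
        with pytest.raises(ValueError):
            normalize_trimmed_mean(pd.DataFrame({"a": [0.0] * 50}))


class TestBH:
    def test_direct_formula_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_all_ones(self):
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_single_p(self):
        assert bh_adjust([0.3]) == pytest.approx([0.3])

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        for _ in range(5):
            p = rng.uniform(size=50)
            _, q_sm, _, _ = multipletests(p, method="fdr_bh")
            assert np.allclose(bh_adjust(p), q_sm)

    def test_invariants(self):
        rng = np.random.default_rng(3)
        p = rng.uniform(size=200)
        q = bh_adjust(p)
        assert (q >= p - 1e-12).all() and (q <= 1).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestCallDE:
    def test_recovers_planted_probes(self):
        cfg = SimConfig(seed=21)
        matrix, truth = simulate_microarray(cfg)
        res = call_de(normalize_trimmed_mean(matrix), ["A_1", "A_2"], ["B_1", "B_2"])
        true_up = set(truth.loc[truth.direction == "up", "probe"])
        true_down = set(truth.loc[truth.direction == "down", "probe"])
        sens = (len(res.up & true_up) + len(res.down & true_down)) / len(truth)
        assert sens >= 0.9

    def test_identical_groups_give_no_calls(self):
        rng = np.random.default_rng(4)
        m = pd.DataFrame(2.0 ** rng.normal(10, 1, size=(200, 2)), columns=["x", "y"])
        res = call_de(m, ["x", "y"], ["x", "y"])
        assert not res.up and not res.down

    def test_swapping_groups_swaps_up_and_down(self):
        cfg = SimConfig(n_probes=500, seed=22)
        matrix, _ = simulate_microarray(cfg)
        ab = call_de(matrix, ["A_1", "A_2"], ["B_1", "B_2"])
        ba = call_de(matrix, ["B_1", "B_2"], ["A_1", "A_2"])
        assert ab.up == ba.down and ab.down == ba.up

    def test_call_invariant(self):
        cfg = SimConfig(n_probes=500, seed=23)
        matrix, _ = simulate_microarray(cfg)
        res = call_de(normalize_trimmed_mean(matrix), ["A_1", "A_2"], ["B_1", "B_2"])
        t = res.table
        up = t["call"] == "up"
        assert ((t.loc[up, "fold_change"] >= 3) & (t.loc[up, "q"] < 0.05)).all()
        down = t["call"] == "down"
        assert ((t.loc[down, "fold_change"] <= 1 / 3) & (t.loc[down, "q"] < 0.05)).all()
        assert (t["q"] >= t["p"] - 1e-12).all()

    def test_single_replicate_rejected(self):
        m = pd.DataFrame({"a": [1.0], "b": [2.0]})
        with pytest.raises(ValueError):
            call_de(m, ["a"], ["b"])


class TestVenn:
    def test_pairwise_intersection(self):
        out = venn({"A": {1, 2, 3}, "B": {2, 3, 4}})
        assert out["A&B"] == 2
        assert out["A_only"] == 1 and out["B_only"] == 1

    def test_disjoint(self):
        out = venn({"A": {1}, "B": {2}})
        assert out["A&B"] == 0

    def test_regions_sum_to_union(self):
        sets = {"A": {1, 2, 3, 7}, "B": {2, 3, 4}, "C": {3, 4, 5, 6}}
        out = venn(sets)
        exclusive = [v for k, v in out.items() if k.endswith("_only")]
        assert sum(exclusive) == out["union"] == len(set().union(*sets.values()))


class TestContrastCorrelation:
    def test_proportional_vectors(self):
        d = np.array([1.0, -2.0, 3.0, 0.5])
        r, p = contrast_correlation(d, 2 * d)
        assert r == pytest.approx(1.0)

    def test_anti_proportional(self):
        d = np.array([1.0, -2.0, 3.0, 0.5])
        r, _ = contrast_correlation(d, -d)
        assert r == pytest.approx(-1.0)

    def test_zero_variance_raises(self):
        with pytest.raises(ValueError):
            contrast_correlation([1, 1, 1], [1, 2, 3])

    def test_shared_planted_direction_correlates(self):
        cfg = SimConfig(n_probes=1000, seed=24)
        matrix, _ = simulate_microarray(cfg)
        norm = normalize_trimmed_mean(matrix)
        log = np.log2(norm + 1)
        # two half-replicate contrasts sharing the planted DE structure
        d1 = log["B_1"] - log["A_1"]
        d2 = log["B_2"] - log["A_2"]
        r, p = contrast_correlation(d1, d2)
        assert r > 0 and p < 0.001


class TestClustering:
    def test_identical_features_merge_at_zero(self):
        m = pd.DataFrame([[0, 1, 2, 3], [0, 1, 2, 3], [3, 1, 0, 2],
                          [5, 1, 2, 0], [0, 5, 1, 1], [2, 0, 5, 1]],
                         index=list("abcdef"), dtype=float)
        link, labels, dropped = cluster_features(m, k=3)
        assert link[0][2] == pytest.approx(0.0)  # first merge at distance 0
        assert labels["a"] == labels["b"]
        assert not dropped

    def test_k_equals_n_gives_singletons(self):
        rng = np.random.default_rng(5)
        m = pd.DataFrame(rng.normal(size=(5, 4)))
        _, labels, _ = cluster_features(m, k=5)
        assert labels.nunique() == 5

    def test_three_feature_hand_trace(self):
        """Merge order and heights match a hand UPGMA trace on 1 - r."""
        x1 = np.array([0.0, 1.0, 2.0, 3.0])
        x2 = np.array([0.0, 1.1, 1.9, 3.2])
        x3 = np.array([3.0, 2.0, 1.0, 0.0])
        m = pd.DataFrame([x1, x2, x3], index=["f1", "f2", "f3"])

        def d(u, v):
            return 1 - np.corrcoef(u, v)[0, 1]

        d12, d13, d23 = d(x1, x2), d(x1, x3), d(x2, x3)
        link, labels, _ = cluster_features(m, k=2)
        # closest pair (f1, f2) merges first at d12, then joins f3 at the
        # average of d13 and d23
        assert sorted(link[0][:2]) == [0, 1]
        assert link[0][2] == pytest.approx(d12)
        assert link[1][2] == pytest.approx((d13 + d23) / 2)
        assert labels["f1"] == labels["f2"] != labels["f3"]

    def test_constant_feature_dropped_with_warning(self):
        m = pd.DataFrame([[1, 1, 1, 1], [0, 1, 2, 3], [3, 1, 2, 0],
                          [1, 4, 0, 2]], index=list("abcd"), dtype=float)
        with pytest.warns(UserWarning, match="constant"):
            _, labels, dropped = cluster_features(m, k=2)
        assert dropped == ["a"] and "a" not in labels.index

    def test_newick_roundtrip_has_all_leaves(self):
        rng = np.random.default_rng(6)
        m = pd.DataFrame(rng.normal(size=(6, 4)), index=[f"g{i}" for i in range(6)])
        link, labels, _ = cluster_features(m, k=2)
        nwk = linkage_to_newick(link, list(labels.index))
        assert nwk.endswith(";") and all(f"g{i}" in nwk for i in range(6))


class TestScreenResponsive:
    def make_counts(self, s_values, base=1000.0):
        rows = {}
        for i, s in enumerate(s_values):
            # plant R_wt = s, R_mut = 1 by construction
            rows[f"m{i}"] = {"wt_24C": base, "wt_4C": base * s,
                             "net2_24C": base, "net2_4C": base}
        frame = pd.DataFrame.from_dict(rows, orient="index")
        # ballast row equalizes library totals so CPM leaves ratios untouched
        total = frame.sum(axis=0).max() + 10 * base
        frame.loc["ballast"] = total - frame.sum(axis=0)
        return frame

    def test_equal_responsiveness_not_selected(self):
        counts = pd.DataFrame({"wt_24C": [100, 200], "wt_4C": [400, 200],
                               "net2_24C": [100, 200], "net2_4C": [400, 200]},
                              index=["m1", "m2"], dtype=float)
        table = screen_responsive(counts, "wt", "net2")
        assert not table["selected"].any()
        assert np.allclose(table["screen_statistic"], 1.0)

    def test_threshold_one_selects_everything_off_unity(self):
        counts = self.make_counts([4.0, 0.2, 1.0])
        table = screen_responsive(counts, "wt", "net2", threshold=1.0)
        assert table.loc[["m0", "m1", "m2"], "selected"].tolist() == [True, True, False]

    def test_cpm_makes_screen_scale_invariant(self):
        counts = self.make_counts([8.0, 1.0, 0.125, 1.0])
        t1 = screen_responsive(counts, "wt", "net2")
        scaled = counts.copy()
        scaled["wt_4C"] *= 37.0  # library-size change only
        t2 = screen_responsive(scaled, "wt", "net2")
        assert np.allclose(t1["screen_statistic"], t2["screen_statistic"], rtol=1e-3)

    def test_missing_library_raises(self):
        with pytest.raises(ValueError, match="missing"):
            screen_responsive(pd.DataFrame({"wt_24C": [1]}), "wt", "net2")


class TestDdct:
    def make_table(self, dct_by_sample, control_ct=20.0):
        rows = []
        for sample, dct in dct_by_sample.items():
            for rep in (1, 2, 3):
                rows.append({"gene": "actin", "sample": sample, "ct": control_ct})
                rows.append({"gene": "tgt", "sample": sample, "ct": control_ct + dct})
        return pd.DataFrame(rows)

    def test_calibrator_yields_one(self):
        t = self.make_table({"cal": 5.0})
        assert ddct(t, "tgt", "actin", "cal", "cal") == pytest.approx(1.0)

    @pytest.mark.parametrize("ddct_value,expected", [(1.0, 0.5), (-2.0, 4.0)])
    def test_closed_form(self, ddct_value, expected):
        t = self.make_table({"cal": 5.0, "s": 5.0 + ddct_value})
        assert ddct(t, "tgt", "actin", "s", "cal") == pytest.approx(expected)

    def test_missing_ct_raises(self):
        t = self.make_table({"cal": 5.0})
        with pytest.raises(ValueError):
            ddct(t, "tgt", "actin", "nope", "cal")

    def test_recovers_planted_relative_expression(self):
        cfg = SimConfig(seed=31)
        ct, truth = simulate_ct_table(cfg)
        for gene in truth.index:
            for sample in truth.columns:
                rel = ddct(ct, gene, "actin", sample, "wt_24C")
                assert rel == pytest.approx(truth.loc[gene, sample], rel=0.15)
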
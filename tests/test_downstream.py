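import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lncmap.downstream import (
    GeneSetCollection,
    category_anova,
    category_counts,
    compare_proximity,
    group_differential,
    hallmark_profile,
    proliferation_groups,
    quartile_fold_change,
    top_k_partners,
    treatment_screen,
    tss_proximity,
    tukey_fences,
)
from test_modulemap import _network_from_coefs


class TestTopKPartners:
    def _net(self, seed=0, n_genes=50):
        rng = np.random.default_rng(seed)
        genes = [f"G{i:03d}" for i in range(n_genes)]
        coef = pd.DataFrame(rng.normal(size=(1, n_genes)), index=["L0"],
                            columns=genes)
        return coef, _network_from_coefs(coef)

    def test_k1_positive_is_argmax(self):
        coef, net = self._net()
        assert top_k_partners(net, "L0", k=1, direction="positive") == [
            coef.loc["L0"].idxmax()
        ]

    def test_k_larger_than_partner_count_returns_all(self):
        _, net = self._net(n_genes=5)
        with pytest.warns(UserWarning, match="only 5"):
            out = top_k_partners(net, "L0", k=200, direction="negative")
        assert len(out) == 5

    def test_matches_bruteforce_sort(self):
        coef, net = self._net(seed=1, n_genes=300)
        got = top_k_partners(net, "L0", k=200, direction="positive")
        expected = list(coef.loc["L0"].sort_values(ascending=False).index[:200])
        assert got == expected
        got_neg = top_k_partners(net, "L0", k=200, direction="negative")
        expected_neg = list(coef.loc["L0"].sort_values().index[:200])
        assert got_neg == expected_neg


class TestHallmarkProfile:
    def test_disjoint_partner_list_empty_profile(self):
        universe = [f"G{i}" for i in range(100)]
        sets = GeneSetCollection({"S1": universe[50:70]}, label="h",
                                 categories={"S1": "signaling"})
        prof = hallmark_profile("L0", {"positive": universe[:10]}, sets, universe)
        assert len(prof) == 0

    def test_planted_suppressor_counts_negative_direction(self):
        universe = [f"G{i}" for i in range(200)]
        prolif = universe[:30]
        sets = GeneSetCollection(
            {"HALLMARK_E2F_TARGETS": prolif},
            label="h", categories={"HALLMARK_E2F_TARGETS": "proliferation"},
        )
        prof = hallmark_profile(
            "L0", {"negative": prolif[:20], "positive": universe[100:120]},
            sets, universe,
        )
        assert set(prof["direction"]) == {"negative"}
        assert (prof["category"] == "proliferation").all()

    def test_category_counts_equal_recount(self):
        rng = np.random.default_rng(2)
        rows = []
        cats = ["proliferation", "signaling", "immune"]
        for i in range(30):
            rows.append(
                {"lncrna_id": f"L{i % 7}", "direction": "positive",
                 "set_name": f"S{i}", "category": cats[int(rng.integers(3))]}
            )
        prof = pd.DataFrame(rows)
        counts = category_counts(prof, categories=cats)
        for c in cats:
            assert counts[c] == prof[prof.category == c].lncrna_id.nunique()


class TestCategoryAnova:
    def test_identical_counts_give_null(self):
        table = pd.DataFrame(np.full((4, 6), 7.0))
        f, p = category_anova(table)
        assert (f, p) == (0.0, 1.0)

    def test_two_categories_reduce_to_squared_t(self):
        rng = np.random.default_rng(3)
        table = pd.DataFrame(rng.normal(size=(2, 10)))
        f, p = category_anova(table)
        t = stats.ttest_ind(table.iloc[0], table.iloc[1]).statistic
        assert f == pytest.approx(t**2)

    def test_matches_sum_of_squares_formula(self):
        rng = np.random.default_rng(4)
        table = pd.DataFrame(rng.normal(size=(5, 8)))
        f, _ = category_anova(table)
        groups = table.to_numpy()
        grand = groups.mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        k, n = groups.shape[0], groups.size
        f_manual = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert f == pytest.approx(f_manual)


class TestProliferationGroups:
    def test_eight_samples_two_per_extreme(self):
        rng = np.random.default_rng(5)
        expr = pd.DataFrame(rng.normal(size=(10, 8)),
                            index=[f"G{i}" for i in range(10)],
                            columns=[f"s{j}" for j in range(8)])
        groups = proliferation_groups(expr, {"set": [f"G{i}" for i in range(10)]})
        assert (groups["group"] == "lower").sum() == 2
        assert (groups["group"] == "upper").sum() == 2

    def test_constant_matrix_uses_tie_rule(self):
        expr = pd.DataFrame(np.ones((3, 8)), index=["a", "b", "c"],
                            columns=[f"s{j}" for j in range(8)])
        groups = proliferation_groups(expr, {"set": ["a", "b", "c"]})
        # ties broken by sample id: first two ids lower, last two upper
        assert list(groups[groups.group == "lower"].index) == ["s0", "s1"]
        assert list(groups[groups.group == "upper"].index) == ["s6", "s7"]

    def test_scores_equal_row_subset_means(self):
        rng = np.random.default_rng(6)
        expr = pd.DataFrame(rng.normal(size=(20, 12)),
                            index=[f"G{i}" for i in range(20)],
                            columns=[f"s{j}" for j in range(12)])
        genes = [f"G{i}" for i in range(0, 20, 3)]
        groups = proliferation_groups(expr, {"a": genes[:3], "b": genes[3:]})
        np.testing.assert_allclose(groups["score"], expr.loc[genes].mean(axis=0))


class TestGroupDifferential:
    def test_identical_groups_not_significant(self):
        rng = np.random.default_rng(7)
        half = pd.DataFrame(rng.exponential(1, size=(5, 6)),
                            index=[f"G{i}" for i in range(5)],
                            columns=[f"a{j}" for j in range(6)])
        dup = half.copy()
        dup.columns = [f"b{j}" for j in range(6)]
        expr = pd.concat([half, dup], axis=1)
        groups = pd.Series(["upper"] * 6 + ["lower"] * 6, index=expr.columns)
        res = group_differential(expr, groups)
        assert (res["p"] >= 0.99).all()
        np.testing.assert_allclose(res["log2fc"], 0.0, atol=1e-12)

    def test_planted_fourfold_shift_detected(self):
        rng = np.random.default_rng(8)
        n = 50
        base = rng.lognormal(2, 0.2, size=(20, 2 * n))
        expr = pd.DataFrame(base, index=[f"G{i}" for i in range(20)],
                            columns=[f"s{j}" for j in range(2 * n)])
        expr.iloc[0, :n] *= 4.0  # first n samples are the high group
        groups = pd.Series(["upper"] * n + ["lower"] * n, index=expr.columns)
        res = group_differential(expr, groups)
        assert res.iloc[0]["q"] < 0.05
        assert abs(res.iloc[0]["log2fc"] - 2.0) < 0.3

    def test_rank_sum_statistic_equals_enumeration(self):
        # exact U by all-pairs counting at tiny n
        rng = np.random.default_rng(9)
        x = rng.normal(size=6)
        y = rng.normal(size=5)
        u_brute = sum(
            (xi > yj) + 0.5 * (xi == yj) for xi, yj in itertools.product(x, y)
        )
        u_scipy = stats.mannwhitneyu(x, y, alternative="two-sided").statistic
        assert u_scipy == pytest.approx(u_brute)


class TestTreatmentScreen:
    def _counts(self, seed=10, n=30, reps=4):
        rng = np.random.default_rng(seed)
        idx = pd.Index([f"L{i:03d}" for i in range(n)], name="lncrna_id")
        treated = pd.DataFrame(rng.poisson(200, size=(n, reps)), index=idx)
        control = pd.DataFrame(rng.poisson(200, size=(n, reps)), index=idx)
        return treated, control

    def test_identical_matrices_give_zero_fold_changes(self):
        treated, _ = self._counts()
        res = treatment_screen(treated, treated.copy())
        np.testing.assert_allclose(res.log2fc, 0.0, atol=1e-12)
        assert res.up == [] and res.down == []

    def test_doubled_feature_approaches_log2fc_one(self):
        # deep, equal libraries with many unchanged features: the doubled
        # feature's estimate converges to log2FC = 1 (composition effect
        # vanishes as the background grows)
        idx = pd.Index([f"F{i:02d}" for i in range(50)], name="f")
        control = pd.DataFrame(np.full((50, 3), 100_000), index=idx)
        treated = control.copy()
        treated.loc["F00"] *= 2
        res = treatment_screen(treated, control)
        assert res.log2fc["F00"] == pytest.approx(1.0, abs=0.05)
        assert (
            res.log2fc["F00"] - res.log2fc["F01"] == pytest.approx(1.0, abs=1e-3)
        )

    def test_swap_symmetry_negates_log2fc_exactly(self):
        treated, control = self._counts(seed=11)
        a = treatment_screen(treated, control)
        b = treatment_screen(control, treated)
        np.testing.assert_allclose(a.log2fc, -b.log2fc, atol=1e-12)
        assert a.up == b.down and a.down == b.up

    def test_feature_never_up_and_down(self):
        treated, control = self._counts(seed=12)
        res = treatment_screen(treated, control, fc_threshold=1.05)
        assert not set(res.up) & set(res.down)


class TestTssProximity:
    def _tss(self, positions, chrom="chr1"):
        return pd.DataFrame(
            {
                "lncrna_id": [f"L{i}" for i in range(len(positions))],
                "chrom": chrom,
                "strand": "+",
                "tss_position": positions,
            }
        )

    def test_peak_spanning_tss_counted(self):
        tss = self._tss([5000])
        peaks = pd.DataFrame({"chrom": ["chr1"], "start": [4900], "end": [5100]})
        assert tss_proximity([peaks], tss, window=0)["L0"] == 1

    def test_boundary_point_peak_at_window_plus_one(self):
        tss = self._tss([50_000])
        t0 = 50_000 - 1
        inside = pd.DataFrame(
            {"chrom": ["chr1"], "start": [t0 + 10_000], "end": [t0 + 10_001]}
        )
        outside = pd.DataFrame(
            {"chrom": ["chr1"], "start": [t0 + 10_001], "end": [t0 + 10_002]}
        )
        assert tss_proximity([inside], tss, window=10_000)["L0"] == 1
        assert tss_proximity([outside], tss, window=10_000)["L0"] == 0

    def test_matches_bruteforce_distance_scan(self):
        rng = np.random.default_rng(13)
        tss = self._tss(list(rng.integers(1, 1_000_000, size=30)))
        peaksets = []
        for _ in range(5):
            starts = rng.integers(0, 1_000_000, size=50)
            peaksets.append(
                pd.DataFrame(
                    {"chrom": "chr1", "start": starts, "end": starts + 200}
                )
            )
        counts = tss_proximity(peaksets, tss, window=10_000)
        for i, lnc in enumerate(counts.index):
            t0 = tss["tss_position"].iloc[i] - 1
            expected = 0
            for peaks in peaksets:
                hit = any(
                    s <= t0 + 10_000 and e > t0 - 10_000
                    for s, e in zip(peaks["start"], peaks["end"])
                )
                expected += hit
            assert counts[lnc] == expected

    def test_candidate_vs_background_comparison(self):
        counts = pd.Series(
            [9, 10, 8, 9, 1, 0, 2, 1, 0, 1, 2, 0],
            index=[f"L{i}" for i in range(12)],
        )
        _, p = compare_proximity(counts, ["L0", "L1", "L2", "L3"])
        assert p < 0.05


class TestQuartileFoldChange:
    def test_independent_anchor_near_zero(self):
        rng = np.random.default_rng(14)
        expr = pd.DataFrame(rng.lognormal(2, 0.3, size=(40, 100)),
                            index=[f"G{i}" for i in range(40)],
                            columns=[f"s{j}" for j in range(100)])
        fc = quartile_fold_change(expr, "G0", [f"G{i}" for i in range(1, 40)])
        assert abs(fc.mean()) < 0.15

    def test_self_anchor_strongly_positive(self):
        rng = np.random.default_rng(15)
        expr = pd.DataFrame(rng.lognormal(2, 0.5, size=(3, 60)),
                            index=["A", "B", "C"],
                            columns=[f"s{j}" for j in range(60)])
        fc = quartile_fold_change(expr, "A", ["A"])
        assert fc["A"] > 0.5

    def test_planted_anticorrelated_targets_negative(self):
        rng = np.random.default_rng(16)
        n = 120
        anchor = rng.normal(size=n)
        pos = np.exp(0.8 * anchor[None, :] + 0.3 * rng.normal(size=(10, n)) + 2)
        neg = np.exp(-0.8 * anchor[None, :] + 0.3 * rng.normal(size=(10, n)) + 2)
        expr = pd.DataFrame(
            np.vstack([np.exp(anchor)[None, :], pos, neg]),
            index=["A"] + [f"P{i}" for i in range(10)] + [f"N{i}" for i in range(10)],
            columns=[f"s{j}" for j in range(n)],
        )
        fc = quartile_fold_change(expr, "A", list(expr.index[1:]))
        pos_fc = fc[[f"P{i}" for i in range(10)]]
        neg_fc = fc[[f"N{i}" for i in range(10)]]
        assert (neg_fc < 0).all()
        p = stats.mannwhitneyu(pos_fc, neg_fc, alternative="two-sided").pvalue
        assert p < 0.05


class TestTukeyFences:
    def test_one_to_ten_no_outliers(self):
        assert not tukey_fences(range(1, 11)).any()

    def test_extreme_value_flagged(self):
        flags = tukey_fences([1, 2, 3, 4, 100])
        assert list(flags) == [False, False, False, False, True]

    def test_matches_literal_rule(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            v = rng.standard_t(df=3, size=40)
            q1, q3 = np.percentile(v, [25, 75])
            iqr = q3 - q1
            expected = (v < q1 - 1.5 * iqr) | (v > q3 + 1.5 * iqr)
            assert (tukey_fences(v) == expected).all()
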
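"""Normalization, fold changes, KS comparisons, BH correction, volcano."""

import numpy as np
import pandas as pd
import pytest

from piregulon.expression_response import (
    CountMatrix,
    benjamini_hochberg,
    compare_target_tiers,
    feature_volcano_table,
    ks_two_sample,
    log2_fold_change,
    normalize_counts,
    signed_ks,
    size_factors,
)

from conftest import ks_sup_oracle


def matrix_of(data, conditions=None):
    df = pd.DataFrame(data)
    conditions = conditions or {c: ("WT" if c.startswith("WT") else "KO") for c in df.columns}
    return CountMatrix(df, conditions)


class TestNormalizeCounts:
    def test_identical_samples_have_unit_size_factors(self):
        counts = pd.DataFrame({"WT_1": [10, 20, 30], "WT_2": [10, 20, 30]})
        sf = size_factors(counts)
        assert np.allclose(sf, 1.0)
        m = matrix_of({"WT_1": [10, 20, 30], "KO_1": [10, 20, 30]})
        assert np.allclose(normalize_counts(m), m.counts)

    def test_doubled_sample_normalizes_back(self):
        a = np.array([11, 40, 7, 100, 3])
        counts = pd.DataFrame({"WT_1": a, "KO_1": 2 * a})
        sf = size_factors(counts)
        assert sf["KO_1"] / sf["WT_1"] == pytest.approx(2.0)
        m = matrix_of({"WT_1": a, "KO_1": 2 * a})
        norm = normalize_counts(m)
        assert np.allclose(norm["WT_1"], norm["KO_1"])

    def test_size_factors_match_stepwise_recomputation(self):
        rng = np.random.default_rng(0)
        counts = pd.DataFrame(
            rng.negative_binomial(10, 0.05, size=(200, 4)),
            columns=["WT_1", "WT_2", "KO_1", "KO_2"],
        )
        sf = size_factors(counts)
        mat = counts.to_numpy(float)
        log_geo = np.log(mat).mean(axis=1)  # -inf where any zero
        keep = np.isfinite(log_geo)
        for j, col in enumerate(counts.columns):
            ratios = mat[keep, j] / np.exp(log_geo[keep])
            assert sf[col] == pytest.approx(np.median(ratios))

    def test_all_zero_matrix_is_error(self):
        with pytest.raises(ValueError):
            size_factors(pd.DataFrame({"WT_1": [0, 0], "KO_1": [0, 0]}))


class TestLog2FoldChange:
    def test_equal_means_give_zero(self):
        m = matrix_of({"WT_1": [10], "KO_1": [10]})
        lfc = log2_fold_change(m.counts.astype(float), m, "WT", "KO")
        assert lfc.iloc[0] == 0.0

    def test_pseudocount_arithmetic(self):
        m = matrix_of({"WT_1": [1], "KO_1": [7]})
        lfc = log2_fold_change(m.counts.astype(float), m, "WT", "KO", pseudocount=1)
        assert lfc.iloc[0] == pytest.approx(2.0)  # log2(8/2)

    def test_antisymmetric_under_condition_swap(self):
        rng = np.random.default_rng(1)
        m = matrix_of({"WT_1": rng.integers(0, 100, 50), "KO_1": rng.integers(0, 100, 50)})
        norm = m.counts.astype(float)
        ab = log2_fold_change(norm, m, "WT", "KO")
        ba = log2_fold_change(norm, m, "KO", "WT")
        assert np.allclose(ab, -ba)

    def test_unknown_condition_is_error(self):
        m = matrix_of({"WT_1": [1], "KO_1": [2]})
        with pytest.raises(ValueError):
            log2_fold_change(m.counts.astype(float), m, "WT", "HET")


class TestKsTwoSample:
    def test_identical_samples_give_zero(self):
        x = [1.0, 2.0, 3.0]
        d, p = ks_two_sample(x, x)
        assert d == 0.0

    def test_disjoint_supports_give_one(self):
        d, _ = ks_two_sample([0.0, 0.0, 0.0], [1.0, 1.0, 1.0])
        assert d == 1.0

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_statistic_equals_bruteforce_sup(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1.2, size=40)
        d, _ = ks_two_sample(x, y)
        assert d == pytest.approx(ks_sup_oracle(x, y), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=25)
        y = rng.normal(0.3, size=35)
        d1, _ = ks_two_sample(x, y)
        d2, _ = ks_two_sample(np.exp(x), np.exp(y))
        assert d1 == pytest.approx(d2, abs=1e-12)

    def test_empty_sample_is_error(self):
        with pytest.raises(ValueError):
            ks_two_sample([], [1.0])

    def test_signed_ks_positive_for_right_shift(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=200)
        assert signed_ks(base + 1.0, base) > 0
        assert signed_ks(base - 1.0, base) < 0


class TestBenjaminiHochberg:
    def test_single_small_p_rejected(self):
        adj, rej = benjamini_hochberg([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_hand_stepped_toy_vector(self):
        adj, rej = benjamini_hochberg([0.01, 0.02, 0.03, 0.9])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.9])
        assert rej.tolist() == [True, True, True, False]

    def test_all_ones_rejects_nothing(self):
        adj, rej = benjamini_hochberg([1.0] * 5)
        assert not rej.any()

    def test_out_of_range_p_is_error(self):
        with pytest.raises(ValueError):
            benjamini_hochberg([0.5, 1.5])

    def test_matches_statsmodels_and_is_monotone(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(6)
        p = rng.random(100)
        adj, rej = benjamini_hochberg(p, alpha=0.1)
        sm_rej, sm_adj, *_ = multipletests(p, alpha=0.1, method="fdr_bh")
        assert np.allclose(adj, sm_adj)
        assert (rej == sm_rej).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()


class TestCompareTargetTiers:
    def test_identical_tiers_give_zero_d(self):
        rng = np.random.default_rng(7)
        vals = pd.Series(rng.normal(size=30), index=[f"g{i}" for i in range(30)])
        tiers = {"top": [f"g{i}" for i in range(10)]}
        lfc = pd.concat([vals, vals.rename(lambda s: s + "b"), vals.rename(lambda s: s + "c")])
        comparison = compare_target_tiers(
            lfc,
            {"top": [f"g{i}" for i in range(30)],
             "lower": [f"g{i}b" for i in range(30)],
             "nontarget": [f"g{i}c" for i in range(30)]},
        )
        assert np.allclose(comparison.pairwise["D"], 0.0)

    def test_overlapping_tiers_rejected(self):
        lfc = pd.Series([1.0, 2.0], index=["a", "b"])
        with pytest.raises(ValueError, match="overlap"):
            compare_target_tiers(lfc, {"top": ["a"], "lower": ["a", "b"]})

    def test_single_member_tiers_are_valid(self):
        lfc = pd.Series([1.0, 2.0], index=["a", "b"])
        comparison = compare_target_tiers(lfc, {"top": ["a"], "nontarget": ["b"]})
        assert len(comparison.pairwise) == 1
        assert comparison.pairwise["D"].iloc[0] == 1.0

    def test_empty_tier_skipped_with_remaining_pairs_intact(self):
        lfc = pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"])
        comparison = compare_target_tiers(
            lfc, {"top": ["a"], "lower": [], "nontarget": ["b", "c"]}
        )
        assert set(comparison.groups) == {"top", "nontarget"}
        assert len(comparison.pairwise) == 1


class TestFeatureVolcanoTable:
    def test_flat_features_have_zero_lfc_and_p_one(self):
        # constant per row, so size factors are 1 and the features stay flat
        m = matrix_of({
            "WT_1": [50, 20], "WT_2": [50, 20], "WT_3": [50, 20],
            "KO_1": [50, 20], "KO_2": [50, 20], "KO_3": [50, 20],
        })
        table = feature_volcano_table(m, "WT", "KO")
        assert np.allclose(table["log2fc"], 0.0)
        assert (table["p"] == 1.0).all()

    def test_single_derepressed_feature_dominates_and_rejections_are_specific(self):
        """One strongly shifted feature among 1,000 nulls ranks first by
        p-value in nearly every seeded run, and whenever the BH step
        rejects anything at n = 3 vs 3, it rejects exactly that feature.
        (A Welch t-test at three replicates per group cannot push p far
        below ~1e-3, so guaranteed BH rejection against 1,000 features
        is not achievable with this test; specificity is.)"""
        rng = np.random.default_rng(8)
        top_ranked = 0
        n_runs = 25
        for _ in range(n_runs):
            null = rng.negative_binomial(20, 20 / (20 + 500), size=(1000, 6))
            ko_up = rng.negative_binomial(20, 20 / (20 + 5000), size=3)
            null[0, 3:] = ko_up
            m = matrix_of(pd.DataFrame(
                null, columns=["WT_1", "WT_2", "WT_3", "KO_1", "KO_2", "KO_3"],
                index=[f"f{i}" for i in range(1000)],
            ))
            table = feature_volcano_table(m, "WT", "KO")
            assert table["log2fc"].abs().idxmax() == "f0"
            # within the top 2% of p-values (a null can fluke a tighter
            # variance at n=3, so exact top rank is not guaranteed)
            assert (table["p"] < table.loc["f0", "p"]).mean() <= 0.02
            top_ranked += table["p"].idxmin() == "f0"
            hits = set(table.index[table["significant"]])
            assert hits <= {"f0"}
        assert top_ranked >= 0.6 * n_runs

    def test_too_few_replicates_gives_fold_change_only(self):
        m = matrix_of({"WT_1": [10, 20], "KO_1": [20, 40]})
        table = feature_volcano_table(m, "WT", "KO")
        assert table["p"].isna().all()
        assert not table["significant"].any()
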
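"""Size factors, NB testing, BH-FDR, enrichment calls and set subtraction."""

import numpy as np
import pandas as pd
import pytest

from wormquant import simulate as sim
from wormquant.enrichment import (
    EnrichmentConfig,
    bh_fdr,
    call_enrichment,
    fold_change,
    nb_test,
    permutation_test,
    run_enrichment_pipeline,
    size_factors,
    subtract_sets,
    validate_markers,
)


def bh_oracle(p):
    """Brute-force BH: q_i = min over tails of m * p_(j) / j, clipped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    sorted_p = p[order]
    for i in range(m):
        q[order[i]] = min(
            1.0, min(m * sorted_p[j] / (j + 1) for j in range(i, m))
        )
    return q


class TestSizeFactors:
    def test_identical_samples_all_unity(self):
        df = pd.DataFrame({"a": [10, 20, 5], "b": [10, 20, 5], "c": [10, 20, 5]})
        np.testing.assert_allclose(size_factors(df), 1.0)

    def test_doubled_sample_hand_computed_factors(self):
        a = np.array([10, 40, 100, 7])
        df = pd.DataFrame({"a": a, "b": 2 * a})
        f = size_factors(df)
        np.testing.assert_allclose(
            f.values, [1 / np.sqrt(2), np.sqrt(2)], rtol=1e-12
        )

    def test_scaling_one_sample_scales_its_factor(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.poisson(50, size=(200, 4)), columns=list("abcd"))
        base = size_factors(df)
        scaled = df.copy()
        c = 3.0
        scaled["d"] = (scaled["d"] * c).astype(int)
        # recompute-after-scaling oracle: d's factor grows ~c relative to the rest
        f = size_factors(scaled)
        ratio = (f["d"] / base["d"]) / (f["a"] / base["a"])
        assert ratio == pytest.approx(c, rel=0.05)

    def test_all_zero_sample_is_rejected_by_name(self):
        df = pd.DataFrame({"good": [1, 2, 3], "empty": [0, 0, 0]})
        with pytest.raises(ValueError, match="empty"):
            size_factors(df)


class TestNbTest:
    def _null_counts(self, n1=4, n2=3, G=400, disp=0.1, seed=0):
        rng = np.random.default_rng(seed)
        mu = rng.gamma(0.7, 100, G) + 1
        nnb = 1 / disp
        counts = np.column_stack(
            [rng.negative_binomial(nnb, nnb / (nnb + mu)) for _ in range(n1 + n2)]
        )
        df = pd.DataFrame(counts, index=[f"g{i}" for i in range(G)])
        labels = np.array(["a"] * n1 + ["b"] * n2)
        return df, labels

    def test_label_swap_leaves_two_sided_p_unchanged(self):
        df, labels = self._null_counts()
        p1 = nb_test(df, labels)["p"]
        swapped = np.where(labels == "a", "b", "a")
        p2 = nb_test(df, swapped)["p"]
        np.testing.assert_allclose(p1, p2, rtol=1e-9)

    def test_identical_groups_give_no_small_p(self):
        df, _ = self._null_counts(n1=3, n2=0)
        dup = pd.concat([df, df], axis=1)
        dup.columns = range(6)
        labels = np.array(["a"] * 3 + ["b"] * 3)
        res = nb_test(dup, labels)
        assert res["p"].min() > 0.9

    def test_all_zero_gene_flagged_with_p_one(self):
        df, labels = self._null_counts(G=50)
        df.iloc[0] = 0
        res = nb_test(df, labels)
        assert res["all_zero"].iloc[0] and res["p"].iloc[0] == 1.0

    def test_agrees_with_permutation_oracle_on_null_genes(self):
        """The Wald p ranks genes like the exact permutation reference and
        makes the same calls at the 0.05 level; mid-range p-values deviate
        by at most a few percent (median |dp| ~ 0.02 at 8 vs 8)."""
        from scipy import stats as sps

        df, labels = self._null_counts(n1=8, n2=8, G=300, seed=4)
        p_nb = nb_test(df, labels)["p"].to_numpy()
        p_perm = permutation_test(df, labels, n_perm=1000, seed=9)
        assert np.median(np.abs(p_nb - p_perm)) <= 0.05
        assert sps.spearmanr(p_nb, p_perm).statistic >= 0.95
        assert ((p_nb < 0.05) == (p_perm < 0.05)).mean() >= 0.95

    def test_requires_two_groups_with_two_samples(self):
        df, _ = self._null_counts(G=20)
        with pytest.raises(ValueError, match="2 groups"):
            nb_test(df, np.array(["a"] * 7))
        with pytest.raises(ValueError, match="2 samples"):
            nb_test(df, np.array(["a"] * 6 + ["b"]))


class TestBhFdr:
    def test_hand_applied_step_up_example(self):
        q = bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]))
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p_is_returned_unchanged(self):
        np.testing.assert_allclose(bh_fdr(np.array([0.37])), [0.37])

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            p = rng.random(rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), bh_oracle(p), rtol=1e-12)

    def test_monotone_along_sorted_p(self):
        rng = np.random.default_rng(2)
        p = rng.random(500)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()

    def test_rejects_out_of_range_p(self):
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            bh_fdr(np.array([0.1, 1.7]))


class TestEnrichmentCall:
    def test_printed_wildtype_example_is_enriched(self):
        # ins-17-like row: means 265.6 vs 34.4 at q = 2.37e-6
        flag = call_enrichment(
            np.array([265.6]), np.array([34.4]), np.array([2.37e-6])
        )
        assert flag[0]

    def test_printed_mutant_example_is_not_enriched(self):
        flag = call_enrichment(
            np.array([101.7]), np.array([56.0]), np.array([0.72])
        )
        assert not flag[0]

    def test_q_exactly_at_threshold_fails_strict_inequality(self):
        flag = call_enrichment(np.array([100.0]), np.array([10.0]), np.array([0.05]))
        assert not flag[0]

    def test_zero_reference_mean_reduces_to_fdr_criterion(self):
        flags = call_enrichment(
            np.array([50.0, 50.0]), np.array([0.0, 0.0]), np.array([0.01, 0.5])
        )
        assert flags[0] and not flags[1]


class TestFoldChange:
    @pytest.mark.parametrize(
        "gfp,allcells,expected",
        [
            (265.6, 34.4, 7.7),    # insulin-family wild-type row
            (19547.2, 2917.5, 6.7),  # FLP-family wild-type row
            (67.0, 9.8, 6.8),      # NLP-family wild-type row
            (101.7, 56.0, 1.8),
            (8562.1, 3427.3, 2.5),
            (37.8, 13.3, 2.8),
        ],
    )
    def test_printed_table_rows_to_one_decimal(self, gfp, allcells, expected):
        assert round(fold_change(gfp, allcells), 1) == expected

    def test_equal_means_give_unity(self):
        assert fold_change(42.0, 42.0) == pytest.approx(1.0)

    def test_reciprocal_property(self):
        assert fold_change(8.0, 2.0) * fold_change(2.0, 8.0) == pytest.approx(1.0)

    def test_zero_reference_is_flagged(self):
        assert np.isinf(fold_change(5.0, 0.0))
        assert np.isnan(fold_change(0.0, 0.0))


class TestSubtractSets:
    def test_published_venn_counts(self):
        universe = [f"g{i}" for i in range(1100)]
        shared = set(universe[:421])
        wt = shared | set(universe[421:574])      # 574 total
        mut = shared | set(universe[574:1020])    # 867 total
        out = subtract_sets(wt, mut)
        assert out["counts"] == {
            "wt": 574, "mut": 867, "shared": 421,
            "wt_only": 153, "mut_only": 446, "preferential": 599,
        }

    def test_identical_sets_have_no_preferential_genes(self):
        s = {"a", "b", "c"}
        out = subtract_sets(s, s)
        assert out["counts"]["preferential"] == 0

    def test_counts_match_membership_tally_on_random_sets(self):
        rng = np.random.default_rng(3)
        universe = [f"g{i}" for i in range(500)]
        wt = {g for g in universe if rng.random() < 0.3}
        mut = {g for g in universe if rng.random() < 0.4}
        out = subtract_sets(wt, mut)
        tally = {"shared": 0, "wt_only": 0, "mut_only": 0}
        for g in universe:
            if g in wt and g in mut:
                tally["shared"] += 1
            elif g in wt:
                tally["wt_only"] += 1
            elif g in mut:
                tally["mut_only"] += 1
        for k, v in tally.items():
            assert out["counts"][k] == v
        assert (
            out["counts"]["preferential"]
            == tally["wt_only"] + tally["mut_only"]
        )
        assert out["counts"]["shared"] + out["counts"]["wt_only"] == len(wt)
        assert out["counts"]["shared"] + out["counts"]["mut_only"] == len(mut)


@pytest.fixture(scope="module")
def design():
    cm, truth = sim.simulate_counts(sim.CountSimSpec(seed=13))
    return cm, truth, run_enrichment_pipeline(cm)


class TestPipelineRecovery:
    def test_planted_genes_recovered_with_high_sensitivity(self, design):
        _, truth, res = design
        planted = set(truth.planted_genes)
        sens = len(planted & res.enriched["wt"]) / len(planted)
        assert sens >= 0.9

    def test_empirical_fdr_controlled(self, design):
        _, truth, res = design
        planted = set(truth.planted_genes)
        called = res.enriched["wt"]
        assert len(called - planted) / max(len(called), 1) <= 0.1

    def test_planted_genes_land_in_wt_only_category(self, design):
        _, truth, res = design
        cats = res.categories.loc[truth.planted_genes]
        assert (cats == "wt_only").mean() >= 0.9

    def test_venn_identities_hold(self, design):
        _, _, res = design
        v = res.venn
        assert v["shared"] + v["wt_only"] == v["wt"]
        assert v["shared"] + v["mut_only"] == v["mut"]
        assert v["preferential"] == v["wt_only"] + v["mut_only"]

    def test_marker_validation_on_planted_truth(self, design):
        cm, truth, res = design
        negatives = [g for g in cm.counts.index[:60] if g not in truth.planted_genes][:20]
        report = validate_markers(
            res.tables["wt"], truth.planted_genes[:20], negatives
        )
        assert report["positives_fail"] <= 2
        assert report["negatives_fail"] <= 1

    def test_unknown_marker_listed_as_unresolved(self, design):
        _, _, res = design
        report = validate_markers(res.tables["wt"], ["not-a-gene"], [])
        assert report["unresolved"] == ["not-a-gene"]
        assert report["passed"]

    def test_empty_marker_lists_pass(self, design):
        _, _, res = design
        report = validate_markers(res.tables["wt"], [], [])
        assert report["passed"] and report["status"] == {}


class TestConfigModes:
    def test_log2_quotient_mode_is_available(self):
        cfg = EnrichmentConfig(ratio_mode="log2_quotient")
        flags = call_enrichment(
            np.array([1000.0]), np.array([10.0]), np.array([0.001]), cfg
        )
        assert flags[0]  # log2(1000)/log2(10) ~ 3 > 1

    def test_unknown_ratio_mode_rejected(self):
        with pytest.raises(ValueError, match="ratio_mode"):
            EnrichmentConfig(ratio_mode="bogus")
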
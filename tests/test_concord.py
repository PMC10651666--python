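"""Partition and concordance statistics vs closed-form/brute-force oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from myoaging.concord import (
    concordance_stats,
    geneset_concordance,
    partition_degs,
    pct_upregulated,
    ranked_logp_profile,
)
from myoaging.diffexpr import de_test
from myoaging.errors import StatsUndefinedError, ValidationError
from myoaging.simulate import simulate_counts

from conftest import make_de_result, small_config


class TestPartitionDegs:
    def test_all_nonsignificant_goes_to_neither(self):
        genes = list("abcde")
        dm = make_de_result(genes, [1.0] * 5, [0.1] * 5, "male")
        df = make_de_result(genes, [1.0] * 5, [0.2] * 5, "female")
        part = partition_degs(dm, df)
        assert part.counts() == {"shared": 0, "male_specific": 0, "female_specific": 0, "neither": 5}

    def test_six_gene_toy_matches_exhaustive_enumeration(self):
        genes = [f"g{i}" for i in range(6)]
        pm = [0.001, 0.5, 0.009, 0.02, 0.0001, 0.9]
        pf = [0.002, 0.003, 0.5, 0.011, 0.0005, 0.99]
        part = partition_degs(
            make_de_result(genes, pm, [1] * 6, "male"),
            make_de_result(genes, pf, [1] * 6, "female"),
            alpha=0.01,
        )
        # brute-force set oracle
        expected = {"shared": set(), "male_specific": set(), "female_specific": set(), "neither": set()}
        for g, a, b in zip(genes, pm, pf):
            key = {
                (True, True): "shared",
                (True, False): "male_specific",
                (False, True): "female_specific",
                (False, False): "neither",
            }[(a < 0.01, b < 0.01)]
            expected[key].add(g)
        assert {k: set(getattr(part, k)) for k in expected} == expected

    def test_partition_is_complete_and_disjoint(self, small_sim):
        cm, _ = small_sim
        dm, df = de_test(cm, sex="male"), de_test(cm, sex="female")
        part = partition_degs(dm, df)
        sets = [part.shared, part.male_specific, part.female_specific, part.neither]
        assert part.universe_size == len(dm.genes)
        for a, b in itertools.combinations(sets, 2):
            assert not (a & b)

    def test_swapping_sexes_transposes_the_partition(self):
        genes = list("abcd")
        dm = make_de_result(genes, [0.001, 0.5, 0.001, 0.5], [1] * 4, "male")
        df = make_de_result(genes, [0.5, 0.001, 0.001, 0.5], [1] * 4, "female")
        part = partition_degs(dm, df)
        swapped = partition_degs(df, dm)
        assert swapped.male_specific == part.female_specific
        assert swapped.female_specific == part.male_specific
        assert swapped.shared == part.shared

    def test_mismatched_universes_rejected(self):
        dm = make_de_result(["a", "b"], [0.5, 0.5], [1, 1], "male")
        df = make_de_result(["a", "c"], [0.5, 0.5], [1, 1], "female")
        with pytest.raises(ValidationError, match="2"):
            partition_degs(dm, df)


class TestConcordanceStats:
    def test_identity_line(self):
        x = np.linspace(-3, 3, 10)
        cs = concordance_stats(x, x)
        assert cs.pct_same_direction == 100.0
        assert cs.pearson_r == pytest.approx(1.0)
        assert cs.slope_m == pytest.approx(1.0)
        assert cs.intercept == pytest.approx(0.0, abs=1e-12)

    def test_reflection_line(self):
        x = np.linspace(-3, 3, 10)
        cs = concordance_stats(x, -x)
        assert cs.pct_same_direction == 0.0
        assert cs.pct_opposite == 100.0
        assert cs.pearson_r == pytest.approx(-1.0)
        assert cs.slope_m == pytest.approx(-1.0)

    def test_five_pairs_match_textbook_ols_oracle(self):
        x = np.array([-1.2, 0.4, 1.1, 2.0, -0.3])
        y = np.array([-0.9, 0.1, 1.4, 1.7, 0.2])
        cs = concordance_stats(x, y)
        # closed-form OLS oracle
        b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        a = y.mean() - b * x.mean()
        r = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        resid = y - (a + b * x)
        se_b = np.sqrt(np.sum(resid**2) / 3 / np.sum((x - x.mean()) ** 2))
        p = 2 * stats.t.sf(abs(b / se_b), df=3)
        assert cs.slope_m == pytest.approx(b, abs=1e-10)
        assert cs.intercept == pytest.approx(a, abs=1e-10)
        assert cs.pearson_r == pytest.approx(r, abs=1e-10)
        assert cs.regression_p == pytest.approx(p, abs=1e-10)

    def test_zero_pairs_excluded_from_direction_percentages(self):
        cs = concordance_stats([1.0, -2.0, 0.0, 3.0], [2.0, -1.0, 5.0, 0.0])
        assert cs.n_zero == 2
        assert cs.pct_same_direction == 100.0

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        st.lists(
            st.tuples(
                st.floats(-10, 10, allow_nan=False), st.floats(-10, 10, allow_nan=False)
            ),
            min_size=3,
            max_size=10,
        )
    )
    def test_matches_closed_form_on_random_small_sets(self, pairs):
        x = np.array([p[0] for p in pairs])
        y = np.array([p[1] for p in pairs])
        if np.ptp(x) == 0:
            with pytest.raises(StatsUndefinedError):
                concordance_stats(x, y)
            return
        cs = concordance_stats(x, y)
        b = np.sum((x - x.mean()) * (y - y.mean())) / np.sum((x - x.mean()) ** 2)
        assert cs.slope_m == pytest.approx(b, abs=1e-10)
        nz = (x != 0) & (y != 0)
        if nz.any():
            assert cs.pct_same_direction + cs.pct_opposite == pytest.approx(100.0)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(StatsUndefinedError):
            concordance_stats([1.0], [1.0])
        with pytest.raises(StatsUndefinedError):
            concordance_stats([2.0, 2.0, 2.0], [1.0, 2.0, 3.0])

    def test_noiseless_truth_concordance_and_slope(self):
        # on truth lfc pairs (no estimation) direction agreement is exact
        # and the within-block regression slope equals the attenuation
        _, truth = simulate_counts(small_config(seed=29))
        mb = truth.lfc_pairs("male_block")
        cs = concordance_stats(mb["lfc_male"], mb["lfc_female"])
        assert cs.pct_same_direction == 100.0
        assert cs.slope_m == pytest.approx(0.40, abs=1e-12)
        assert cs.intercept == pytest.approx(0.0, abs=1e-12)


class TestGenesetConcordance:
    def _toy(self):
        genes = [f"g{i}" for i in range(8)]
        pm = [0.001, 0.02, 0.005, 0.5, 0.001, 0.2, 0.009, 0.7]
        pf = [0.002, 0.001, 0.3, 0.5, 0.004, 0.001, 0.8, 0.6]
        lm = [1.0, 0.5, -0.8, 0.1, 2.0, -0.4, 0.9, -0.2]
        lf = [1.2, 0.6, -0.3, 0.2, 1.8, -0.5, 0.4, 0.3]
        return (
            make_de_result(genes, pm, lm, "male"),
            make_de_result(genes, pf, lf, "female"),
            genes,
        )

    def test_whole_universe_equals_unrestricted_stats(self):
        dm, df, genes = self._toy()
        cs = geneset_concordance(dm, df, genes, selection="all_in_list")
        ref = concordance_stats(dm.table["log2fc"], df.table["log2fc"])
        assert cs.slope_m == pytest.approx(ref.slope_m, abs=1e-12)
        assert cs.n_pairs == ref.n_pairs
        assert cs.n_genes_matched == len(genes)

    def test_restriction_equals_manual_filtering(self):
        dm, df, _ = self._toy()
        sub = ["g0", "g2", "g4"]
        cs = geneset_concordance(dm, df, sub)
        ref = concordance_stats(
            dm.table["log2fc"].loc[sub], df.table["log2fc"].loc[sub]
        )
        assert cs.slope_m == pytest.approx(ref.slope_m, abs=1e-12)
        assert cs.pearson_r == pytest.approx(ref.pearson_r, abs=1e-12)

    def test_selection_modes_filter_by_significance(self):
        dm, df, genes = self._toy()
        either = geneset_concordance(dm, df, genes, selection="degs_in_list_either_sex")
        one = geneset_concordance(dm, df, genes, selection="degs_in_list_one_sex")
        # g0,g4 shared; g2,g6 male-only; g1,g5 female-only; g3,g7 neither
        assert either.n_genes_matched == 6
        assert one.n_genes_matched == 4

    def test_case_insensitive_matching(self):
        dm, df, _ = self._toy()
        cs = geneset_concordance(dm, df, ["G0", "g2", "G4"])
        assert cs.n_genes_matched == 3

    def test_no_match_is_an_error(self):
        dm, df, _ = self._toy()
        with pytest.raises(ValidationError, match="nope"):
            geneset_concordance(dm, df, ["zzz"], list_name="nope")


class TestRankedLogpProfile:
    def test_single_gene(self):
        dm = make_de_result(["a"], [0.01], [1.0], "male")
        df = make_de_result(["a"], [0.1], [1.0], "female")
        prof = ranked_logp_profile(dm, df, ["a"])
        assert list(prof.index) == ["a"]

    def test_order_matches_hand_sort(self):
        genes = ["w", "x", "y", "z"]
        dm = make_de_result(genes, [0.001, 0.1, 0.01, 0.5], [1] * 4, "male")
        df = make_de_result(genes, [0.01, 0.1, 0.001, 0.5], [1] * 4, "female")
        prof = ranked_logp_profile(dm, df, genes)
        # average -log10 p: w = (3+2)/2 = 2.5, y = 2.5, x = 1, z = 0.30
        # ties (w, y) break lexicographically
        assert list(prof.index) == ["w", "y", "x", "z"]

    def test_equal_p_gives_lexicographic_order(self):
        genes = ["c", "a", "b"]
        dm = make_de_result(genes, [0.05] * 3, [1] * 3, "male")
        df = make_de_result(genes, [0.05] * 3, [1] * 3, "female")
        assert list(ranked_logp_profile(dm, df, genes).index) == ["a", "b", "c"]


class TestPctUpregulated:
    def test_all_up(self):
        de = make_de_result(["a", "b"], [0.001, 0.002], [1.0, 2.0])
        assert pct_upregulated(de, ["a", "b"]) == 100.0

    def test_three_up_one_down(self):
        de = make_de_result(
            ["a", "b", "c", "d", "e"], [0.001] * 4 + [0.5], [1.0, 2.0, 0.5, -1.0, -9.0]
        )
        assert pct_upregulated(de, ["a", "b", "c", "d", "e"]) == 75.0

    def test_no_degs_flagged_as_nan(self):
        de = make_de_result(["a", "b"], [0.5, 0.9], [1.0, 2.0])
        assert np.isnan(pct_upregulated(de, ["a", "b"]))

    def test_symmetric_signs_give_about_half(self):
        # shared-block signs are drawn +/- with p = 1/2, so the fraction
        # of upregulated DEGs over replicates concentrates near 50%
        vals = []
        for seed in range(25):
            cm, truth = simulate_counts(
                small_config(seed=seed, n_genes_male_block=0,
                             n_genes_female_block=0, n_genes_null=0)
            )
            de = de_test(cm, sex="male")
            shared = truth.table.index[truth.table["block"] == "shared"]
            vals.append(pct_upregulated(de, shared))
        assert np.mean(vals) == pytest.approx(50.0, abs=3.0)
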
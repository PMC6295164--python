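"""Cohort statistics: frequencies, burden, hypergeometric tests, correlations."""

import itertools
import math
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from karyoadapt import (
    GenomeBuild,
    aneuploidy_frequency,
    binarize_matrix,
    copy_correlation_matrix,
    dna_content_change,
    dna_content_change_matrix,
    hypergeometric_point,
    hypergeometric_tail,
    karyotype_pooled_sd,
    pairwise_cooccurrence,
)
from conftest import make_call_matrix


class TestAneuploidyFrequency:
    def test_counts_aneuploid_strains(self):
        calls = pd.DataFrame({"chrA": [2, 1, 1, 2]})
        freq = aneuploidy_frequency(calls, ploidy=1)
        assert freq.loc["chrA", "frequency"] == pytest.approx(0.5)
        assert freq.loc["chrA", "gain_frequency"] == pytest.approx(0.5)

    def test_euploid_cohort_has_zero_frequency(self):
        calls = pd.DataFrame(np.ones((10, 4), dtype=int),
                             columns=list("abcd"))
        assert (aneuploidy_frequency(calls, 1)["frequency"] == 0).all()

    def test_diploid_gains_and_losses_split(self):
        calls = pd.DataFrame({"chrA": [3, 1, 2, 2]})
        freq = aneuploidy_frequency(calls, ploidy=2)
        assert freq.loc["chrA", "gain_frequency"] == pytest.approx(0.25)
        assert freq.loc["chrA", "loss_frequency"] == pytest.approx(0.25)
        assert freq.loc["chrA", "frequency"] == pytest.approx(0.5)

    def test_planted_gain_rate_recovered(self, rng):
        n = 200
        gains = rng.random(n) < 0.6
        calls = pd.DataFrame({"chrA": np.where(gains, 2, 1),
                              "chrB": np.ones(n, dtype=int)})
        freq = aneuploidy_frequency(calls, 1)
        # binomial 99% CI around 0.6 at n=200
        half = 2.576 * math.sqrt(0.6 * 0.4 / n)
        assert abs(freq.loc["chrA", "frequency"] - 0.6) < half


class TestDnaContentChange:
    def genome(self, fractions, ploidy=1):
        total = 1_000_000
        lengths = [int(round(f * total)) for f in fractions]
        return GenomeBuild(tuple((f"c{i}", l) for i, l in enumerate(lengths)),
                           basal_ploidy=ploidy, telomere_exclusion=0)

    def test_euploid_is_zero(self):
        g = self.genome([0.25, 0.25, 0.25, 0.25])
        assert dna_content_change([1, 1, 1, 1], g) == 0.0

    def test_single_gain_counts_its_genome_fraction(self):
        g = self.genome([0.04, 0.32, 0.32, 0.32])
        assert dna_content_change([2, 1, 1, 1], g) == pytest.approx(4.0)

    def test_diploid_burden_normalized_by_ploidy(self):
        g = self.genome([0.04, 0.02, 0.47, 0.47], ploidy=2)
        assert dna_content_change([3, 1, 2, 2], g) == pytest.approx(3.0)

    def test_order_invariance_and_additivity(self, rng):
        fracs = [0.1, 0.2, 0.3, 0.4]
        g = self.genome(fracs)
        calls = np.array([2, 1, 3, 1])
        # additive over disjoint aberration sets
        a = dna_content_change([2, 1, 1, 1], g)
        b = dna_content_change([1, 1, 3, 1], g)
        assert dna_content_change(calls, g) == pytest.approx(a + b)
        # order invariance: permuting chromosomes together with calls
        perm = rng.permutation(4)
        gp = self.genome([fracs[i] for i in perm])
        assert dna_content_change(calls[perm], gp) == pytest.approx(
            dna_content_change(calls, g))

    def test_matrix_variant_matches_scalar(self):
        g = self.genome([0.1, 0.2, 0.3, 0.4])
        calls = pd.DataFrame([[2, 1, 1, 1], [1, 1, 3, 1]],
                             columns=[f"c{i}" for i in range(4)])
        per_strain = dna_content_change_matrix(calls, g)
        for i in range(2):
            assert per_strain.iloc[i] == pytest.approx(
                dna_content_change(calls.iloc[i].to_numpy(), g))


def enumeration_pmf(N, K, n, k):
    """Oracle: enumerate all n-subsets of an N-cohort and count overlaps."""
    success = set(range(K))
    hits = total = 0
    for subset in itertools.combinations(range(N), n):
        total += 1
        hits += len(success.intersection(subset)) == k
    return hits / total


def comb_pmf(N, K, n, k):
    """Oracle: exact rational arithmetic via integer binomials."""
    return Fraction(math.comb(K, k) * math.comb(N - K, n - k), math.comb(N, n))


class TestHypergeometricPoint:
    def test_empty_success_class_is_certain(self):
        assert hypergeometric_point(10, 0, 5, 0) == pytest.approx(1.0)

    def test_outside_support_raises(self):
        with pytest.raises(ValueError):
            hypergeometric_point(10, 8, 8, 0)  # k < K + n - N
        with pytest.raises(ValueError):
            hypergeometric_point(10, 3, 3, 4)  # k > min(K, n)
        with pytest.raises(ValueError):
            hypergeometric_point(10, 11, 3, 1)  # K > N

    @pytest.mark.parametrize("N,K,n,k", [(8, 3, 4, 2), (10, 5, 5, 0),
                                         (12, 6, 4, 3), (11, 2, 7, 1)])
    def test_matches_subset_enumeration(self, N, K, n, k):
        assert hypergeometric_point(N, K, n, k) == pytest.approx(
            enumeration_pmf(N, K, n, k), rel=1e-12)

    def test_matches_exact_combinatorics_for_small_cohorts(self):
        for N in range(1, 21):
            for K in range(N + 1):
                for n in range(N + 1):
                    for k in range(max(0, K + n - N), min(K, n) + 1):
                        assert hypergeometric_point(N, K, n, k) == pytest.approx(
                            float(comb_pmf(N, K, n, k)), rel=1e-10)

    @given(st.integers(1, 200), st.data())
    @settings(max_examples=40, deadline=None)
    def test_sums_to_one_over_support(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        total = sum(hypergeometric_point(N, K, n, k)
                    for k in range(max(0, K + n - N), min(K, n) + 1))
        assert total == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(2, 120), st.data())
    @settings(max_examples=40, deadline=None)
    def test_symmetric_in_K_and_n(self, N, data):
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, K + n - N), min(K, n)))
        assert hypergeometric_point(N, K, n, k) == pytest.approx(
            hypergeometric_point(N, n, K, k), rel=1e-12)

    def test_tail_variant_accumulates_point_probabilities(self):
        lower = sum(hypergeometric_point(20, 8, 10, j) for j in range(0, 4))
        assert hypergeometric_tail(20, 8, 10, 3, "exclusivity") == pytest.approx(lower)
        upper = sum(hypergeometric_point(20, 8, 10, j) for j in range(6, 9))
        assert hypergeometric_tail(20, 8, 10, 6, "enrichment") == pytest.approx(upper)


class TestPairwiseCooccurrence:
    def test_disjoint_events_flagged_exclusive(self):
        calls = make_call_matrix(
            25, {"chr13": (3, range(16)), "chr9": (1, range(16, 23))}, ploidy=2)
        tests = pairwise_cooccurrence(calls, ploidy=2)
        row = tests.iloc[0]
        assert (row["N"], row["K"], row["n"], row["k"]) == (25, 16, 7, 0)
        assert row["direction"] == "exclusivity"
        assert row["p"] == pytest.approx(
            hypergeometric_point(25, 16, 7, 0), rel=1e-12)

    def test_identical_strain_sets_flagged_enriched(self):
        calls = make_call_matrix(
            20, {"chrA": (2, range(6)), "chrB": (2, range(6))}, ploidy=1)
        row = pairwise_cooccurrence(calls, ploidy=1).iloc[0]
        assert row["k"] == row["K"] == row["n"] == 6
        assert row["direction"] == "enrichment"
        assert row["p"] == pytest.approx(hypergeometric_point(20, 6, 6, 6))

    def test_haploid_defaults_to_gain_only_events(self):
        calls = make_call_matrix(
            10, {"chrA": (2, range(4)), "chrB": (0, range(4, 7)),
                 "chrC": (2, range(2, 6))}, ploidy=1)
        tests = pairwise_cooccurrence(calls, ploidy=1)
        events = set(tests["event_a"]) | set(tests["event_b"])
        assert events == {"chrA+", "chrC+"}

    def test_diploid_gain_and_loss_are_distinct_events(self):
        calls = make_call_matrix(
            10, {"chrA": (3, range(4)), "chrB": (1, range(4, 8))}, ploidy=2)
        tests = pairwise_cooccurrence(calls, ploidy=2)
        events = set(tests["event_a"]) | set(tests["event_b"])
        assert events == {"chrA+", "chrB-"}

    def test_null_rate_matches_enumerated_point_statistic(self, rng):
        # independent events at frequency 0.3 in a 1000-strain cohort: the
        # observed firing rate of p_point < 0.05 matches the exact null rate
        # conditional on the margins, computed by enumerating the support
        N, reps, fired, expected_rates = 1000, 200, 0, []
        for _ in range(reps):
            a = rng.random(N) < 0.3
            b = rng.random(N) < 0.3
            calls = pd.DataFrame({"chrA": np.where(a, 2, 1),
                                  "chrB": np.where(b, 2, 1)})
            row = pairwise_cooccurrence(calls, 1).iloc[0]
            fired += row["p"] < 0.05
            K, n = int(row["K"]), int(row["n"])
            rate = sum(hypergeometric_point(N, K, n, k)
                       for k in range(max(0, K + n - N), min(K, n) + 1)
                       if hypergeometric_point(N, K, n, k) < 0.05)
            expected_rates.append(rate)
        observed = fired / reps
        expected = float(np.mean(expected_rates))
        assert abs(observed - expected) < 3 * math.sqrt(expected * (1 - expected) / reps) + 1e-9


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        col = [1.0, 2.0, 1.0, 2.0, 1.1]
        mat = pd.DataFrame({"chrA": col, "chrB": col})
        corr = copy_correlation_matrix(mat, ploidy=1)
        assert corr.pair_r("chrA", "chrB") == pytest.approx(1.0)

    def test_reflected_column_anticorrelates(self):
        col = np.array([1.0, 2.0, 1.0, 2.0, 1.5])
        mat = pd.DataFrame({"chrA": col, "chrB": 2 * 1 - col})
        corr = copy_correlation_matrix(mat, ploidy=1)
        assert corr.pair_r("chrA", "chrB") == pytest.approx(-1.0)

    def test_constant_column_not_included(self):
        mat = pd.DataFrame({"chrA": [1.0, 2.0, 1.0, 2.0],
                            "chrB": [1.0, 1.0, 1.0, 1.0]})
        corr = copy_correlation_matrix(mat, ploidy=1)
        assert not corr.included.loc["chrA", "chrB"]
        assert np.isnan(corr.r.loc["chrA", "chrB"])

    def test_pair_without_observed_aneuploidy_not_included(self):
        # chrB varies but never rounds away from ploidy
        mat = pd.DataFrame({"chrA": [1.0, 2.0, 1.0, 2.0],
                            "chrB": [0.95, 1.05, 0.98, 1.02]})
        corr = copy_correlation_matrix(mat, ploidy=1)
        assert not corr.included.loc["chrA", "chrB"]


class TestPooledSd:
    def test_identical_strains_have_zero_spread(self):
        mat = pd.DataFrame(np.ones((5, 16)))
        assert karyotype_pooled_sd(mat) == 0.0

    def test_single_variable_chromosome_hand_value(self):
        mat = pd.DataFrame(np.ones((2, 16)))
        mat.iloc[0, 0] = 1.0
        mat.iloc[1, 0] = 2.0
        # sample variance 0.5 on one of 16 chromosomes
        assert karyotype_pooled_sd(mat) == pytest.approx(math.sqrt(0.5 / 16))

    def test_scaling_spread_scales_sd_linearly(self, rng):
        base = pd.DataFrame(rng.normal(1.0, 0.2, size=(20, 8)))
        centered = base - base.mean(axis=0)
        assert karyotype_pooled_sd(base.mean(axis=0) + 3 * centered) == pytest.approx(
            3 * karyotype_pooled_sd(base), rel=1e-9)


class TestBinarize:
    def test_matrix_binarization_matches_rounding_rule(self):
        mat = pd.DataFrame({"chrA": [1.02, 1.5, 0.5], "chrB": [1.97, 1.0, 1.2]})
        calls = binarize_matrix(mat, ploidy=1)
        assert list(calls["chrA"]) == [1, 2, 0]
        assert list(calls["chrB"]) == [2, 1, 1]
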
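import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import landbridge as lb
from landbridge.errors import (
    DegenerateComparisonError,
    InvalidInputError,
    SaturationError,
    UndefinedStatisticError,
)
from landbridge.nulldist import (
    fu_fs_from_counts,
    log_unsigned_stirling_row,
    tajima_d_from_counts,
)
from landbridge.popgen import (
    coalescent_null_test,
    count_haplotypes,
    count_site_differences,
    fus_fs,
    k2p_gamma_distance,
    mean_pairwise_differences,
    nucleotide_diversity,
    segregating_sites,
    tajimas_d,
)
from landbridge.simulate import infinite_sites_alignment

from _oracles import exact_fu_fs, exact_tajima_d


class TestSiteDifferences:
    @pytest.mark.parametrize("a,b,expected", [
        ("ACGT", "ACGT", (0.0, 0.0, 4)),
        ("ACGT", "GCGT", (0.25, 0.0, 4)),       # A<->G transition
        ("ACGT", "TCGT", (0.0, 0.25, 4)),       # A<->T transversion
        ("AC-T", "ACGT", (0.0, 0.0, 3)),        # gap site excluded
        ("ACNT", "ATGT", (0.0, 1 / 3, 3)),      # ambiguity excluded, C<->T?
    ])
    def test_examples(self, a, b, expected):
        p, q, length = count_site_differences(a, b)
        if (a, b) == ("ACNT", "ATGT"):
            # C->T at position 2 is a transition, not transversion
            assert (p, q, length) == (1 / 3, 0.0, 3)
        else:
            assert (p, q, length) == expected

    def test_unequal_lengths(self):
        with pytest.raises(InvalidInputError):
            count_site_differences("ACG", "ACGT")

    def test_all_sites_excluded(self):
        with pytest.raises(DegenerateComparisonError):
            count_site_differences("NN--", "ACGT")


class TestK2PGamma:
    def test_zero_distance(self):
        assert k2p_gamma_distance(0.0, 0.0, 0.1705) == 0.0

    def test_jin_nei_formula(self):
        # direct transcription of the Jin-Nei gamma-corrected K2P formula
        p, q, alpha = 0.1, 0.05, 0.1705
        expected = alpha / 2 * ((1 - 2 * p - q) ** (-1 / alpha)
                                + 0.5 * (1 - 2 * q) ** (-1 / alpha) - 1.5)
        assert k2p_gamma_distance(p, q, alpha) == pytest.approx(expected)

    def test_large_alpha_limit(self):
        p, q = 0.1, 0.05
        uncorrected = -0.5 * np.log(1 - 2 * p - q) - 0.25 * np.log(1 - 2 * q)
        assert k2p_gamma_distance(p, q, 1e6) == pytest.approx(uncorrected,
                                                              abs=1e-4)
        assert k2p_gamma_distance(p, q, None) == pytest.approx(uncorrected)

    def test_saturation_raises(self):
        with pytest.raises(SaturationError):
            k2p_gamma_distance(0.45, 0.2, 0.2)


class TestNucleotideDiversity:
    def test_identical_sequences(self):
        aln = lb.Alignment(["a", "b", "c"], ["ACGT" * 5] * 3)
        est = nucleotide_diversity(aln, n_boot=100, seed=0)
        assert est.pi == 0.0
        assert est.se_pi == 0.0

    def test_hand_computed_mean(self):
        aln = lb.Alignment(["a", "b", "c"],
                           ["AAAAAAAAAA", "AAAAAAAAAG", "AAAAAAAGAG"])
        # pairwise (P,Q): ab=(0.1,0), ac=(0.2,0), bc=(0.1,0)
        alpha = 0.1705
        expected = np.mean([k2p_gamma_distance(0.1, 0, alpha),
                            k2p_gamma_distance(0.2, 0, alpha),
                            k2p_gamma_distance(0.1, 0, alpha)])
        est = nucleotide_diversity(aln, alpha=alpha, n_boot=0, seed=0)
        assert est.pi == pytest.approx(expected)

    def test_pi_seed_independent_se_noisy(self, toy_alignment):
        e1 = nucleotide_diversity(toy_alignment, n_boot=400, seed=1)
        e2 = nucleotide_diversity(toy_alignment, n_boot=400, seed=2)
        assert e1.pi == e2.pi
        assert e1.se_pi > 0 and e2.se_pi > 0
        assert abs(e1.se_pi - e2.se_pi) < 0.5 * max(e1.se_pi, e2.se_pi)

    def test_column_permutation_invariance(self, rng, toy_alignment):
        perm = rng.permutation(toy_alignment.n_sites)
        shuffled = lb.Alignment.from_codes(toy_alignment.ids,
                                           toy_alignment.codes[:, perm])
        a = nucleotide_diversity(toy_alignment, n_boot=0, seed=0)
        b = nucleotide_diversity(shuffled, n_boot=0, seed=0)
        assert a.pi == pytest.approx(b.pi)


class TestHaplotypes:
    def test_identical(self):
        aln = lb.Alignment(["a", "b", "c", "d", "e"], ["ACGT"] * 5)
        assert count_haplotypes(aln) == 1

    def test_direct_count(self):
        aln = lb.Alignment(["a", "b", "c", "d"], ["AC", "AC", "AG", "GG"])
        assert count_haplotypes(aln) == 3

    def test_ambiguity_codes_distinct(self):
        aln = lb.Alignment(["a", "b"], ["ACN", "AC-"])
        assert count_haplotypes(aln) == 2

    def test_planted_duplicates(self, rng):
        tree = lb.simulate_coalescent_tree(12, lb.DemographicModel(theta0=1.0),
                                           rng)
        base = infinite_sites_alignment(tree, 30, rng)
        k = count_haplotypes(base)
        dup = lb.Alignment.from_codes(
            base.ids + ["dup0", "dup1"],
            np.vstack([base.codes, base.codes[:2]]),
        )
        assert count_haplotypes(dup) == k


class TestTajimaD:
    def test_hand_oracle_singletons(self):
        # 4 sequences, 3 singleton mutations on one sequence
        aln = lb.Alignment(["a", "b", "c", "d"],
                           ["AAAAAAAAAA", "AAAAAAAAAA", "AAAAAAAAAA",
                            "GAGAGAAAAA"])
        assert tajimas_d(aln) == pytest.approx(exact_tajima_d(aln), abs=1e-9)

    def test_no_segregating_sites(self):
        aln = lb.Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        with pytest.raises(UndefinedStatisticError):
            tajimas_d(aln)

    def test_too_few_sequences(self):
        aln = lb.Alignment(["a", "b", "c"], ["AG", "AA", "GA"])
        with pytest.raises(UndefinedStatisticError):
            tajimas_d(aln)

    def test_null_mean_near_zero(self, rng):
        # neutral constant-size data: E[D] slightly negative, near 0
        vals = []
        for _ in range(800):
            tree = lb.simulate_coalescent_tree(
                30, lb.DemographicModel(theta0=1.0), rng)
            s = int(rng.poisson(2.5 * tree.total_branch_length()))
            if s < 1:
                continue
            vals.append(tajimas_d(infinite_sites_alignment(tree, s, rng)))
        assert -0.25 < np.mean(vals) < 0.10


class TestFuFS:
    def test_ewens_enumeration_oracle(self):
        aln = lb.Alignment(["a", "b", "c", "d", "e"],
                           ["AAAA", "AAAA", "AAAG", "AAGG", "AAGG"])
        assert fus_fs(aln) == pytest.approx(exact_fu_fs(aln), abs=1e-9)

    def test_identical_sequences_undefined(self):
        aln = lb.Alignment(["a", "b", "c"], ["ACGT"] * 3)
        with pytest.raises(UndefinedStatisticError):
            fus_fs(aln)

    def test_star_genealogy_strongly_negative(self, rng):
        # many singleton haplotypes: expansion signature, F_S < 0
        neg = 0
        reps = 40
        for _ in range(reps):
            n, s = 20, 25
            codes = np.full((n, s), 1, dtype=np.uint8)
            cols = rng.integers(0, n, size=s)  # each mutation hits one tip
            codes[cols, np.arange(s)] = 4
            aln = lb.Alignment.from_codes([f"t{i}" for i in range(n)], codes)
            if fus_fs(aln) < 0:
                neg += 1
        assert neg >= 0.95 * reps


class TestBruteForceAgreement:
    def test_fifty_random_toy_alignments(self, rng):
        """D and F_S agree with exact-rational oracles to 1e-6 on random
        small alignments (n <= 8, S <= 12)."""
        checked = 0
        while checked < 50:
            n = int(rng.integers(4, 9))
            s = int(rng.integers(1, 13))
            tree = lb.simulate_coalescent_tree(
                n, lb.DemographicModel(theta0=1.0), rng)
            aln = infinite_sites_alignment(tree, s, rng)
            if segregating_sites(aln) < 1:
                continue
            assert tajimas_d(aln) == pytest.approx(exact_tajima_d(aln),
                                                   abs=1e-6)
            assert fus_fs(aln) == pytest.approx(exact_fu_fs(aln), abs=1e-6)
            checked += 1


class TestStirling:
    def test_small_rows(self):
        assert np.allclose(np.exp(log_unsigned_stirling_row(3)), [0, 2, 3, 1])
        assert np.exp(log_unsigned_stirling_row(5))[2] == pytest.approx(50.0)

    def test_row_sum_is_factorial(self):
        from scipy.special import gammaln
        for n in (6, 15, 40):
            row = log_unsigned_stirling_row(n)
            from scipy.special import logsumexp
            assert logsumexp(row) == pytest.approx(gammaln(n + 1), rel=1e-12)


class TestCoalescentNullTest:
    def test_extreme_statistic_p_zero(self, rng):
        n, s = 20, 25
        codes = np.full((n, s), 1, dtype=np.uint8)
        codes[rng.integers(0, n, size=s), np.arange(s)] = 4
        aln = lb.Alignment.from_codes([f"t{i}" for i in range(n)], codes)
        res = coalescent_null_test(aln, "fu_fs", n_sims=500, seed=0)
        assert res.p_coal <= 0.01
        if res.p_coal == 0.0:
            assert res.p_label == "<0.002"

    def test_undefined_propagates(self):
        aln = lb.Alignment(["a", "b", "c", "d"], ["ACGT"] * 4)
        with pytest.raises(UndefinedStatisticError):
            coalescent_null_test(aln, "tajima_d", n_sims=10, seed=0)

    def test_unknown_statistic(self, toy_alignment):
        with pytest.raises(InvalidInputError):
            coalescent_null_test(toy_alignment, "fay_wu_h", n_sims=10, seed=0)

    def test_two_tailed_at_least_lower(self, rng):
        tree = lb.simulate_coalescent_tree(15, lb.DemographicModel(theta0=1.0),
                                           rng)
        aln = infinite_sites_alignment(tree, 12, rng)
        lo = coalescent_null_test(aln, "tajima_d", n_sims=400, seed=3)
        two = coalescent_null_test(aln, "tajima_d", n_sims=400, seed=3,
                                   two_tailed=True)
        assert 0.0 <= two.p_coal <= 1.0
        # two-tailed doubles the smaller tail
        assert two.p_coal >= min(lo.p_coal, 1.0 - lo.p_coal)

    def test_determinism(self, rng):
        tree = lb.simulate_coalescent_tree(12, lb.DemographicModel(theta0=1.0),
                                           rng)
        aln = infinite_sites_alignment(tree, 10, rng)
        r1 = coalescent_null_test(aln, "tajima_d", n_sims=200, seed=9)
        r2 = coalescent_null_test(aln, "tajima_d", n_sims=200, seed=9)
        assert r1.p_coal == r2.p_coal and r1.observed == r2.observed


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_pi_invariant_under_sequence_reordering(seed):
    rng = np.random.default_rng(seed)
    tree = lb.simulate_coalescent_tree(6, lb.DemographicModel(theta0=1.0), rng)
    variable = infinite_sites_alignment(tree, 8, rng)
    # pad with constant columns so no pair saturates the K2P correction
    pad = np.full((6, 60), 1, dtype=np.uint8)
    aln = lb.Alignment.from_codes(variable.ids,
                                  np.hstack([variable.codes, pad]))
    perm = rng.permutation(aln.n_sequences)
    shuffled = lb.Alignment.from_codes([aln.ids[i] for i in perm],
                                       aln.codes[perm])
    a = nucleotide_diversity(aln, n_boot=0, seed=0).pi
    b = nucleotide_diversity(shuffled, n_boot=0, seed=0).pi
    assert a == pytest.approx(b, abs=1e-12)
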
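import numpy as np
import pytest
import sympy

import landbridge as lb
from landbridge.demography import coalescent_log_density
from landbridge.errors import InvalidInputError
from landbridge.priors import (
    CalibrationPrior,
    OffsetGammaCalibration,
    TruncatedNormalCalibration,
    calibration_log_density,
    ucln_log_density,
)
from landbridge.substitution import (
    discrete_gamma_categories,
    hky_rate_matrix,
    transition_probabilities,
)

from _oracles import enumeration_loglik, gamma_category_means_quadrature


class TestHKYMatrix:
    def test_jc_special_case(self):
        q = hky_rate_matrix(1.0, [0.25] * 4)
        off = q[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1 / 3)
        assert np.allclose(q.sum(axis=1), 0.0)

    def test_stationarity(self, rng):
        for _ in range(5):
            f = rng.dirichlet([5, 5, 5, 5])
            kappa = float(rng.uniform(0.5, 20))
            q = hky_rate_matrix(kappa, f)
            assert np.allclose(f @ q, 0.0, atol=1e-12)
            # unit expected rate
            assert -np.dot(f, np.diag(q)) == pytest.approx(1.0)

    def test_symbolic_oracle(self):
        kappa = 2
        f = [sympy.Rational(3, 10), sympy.Rational(1, 5),
             sympy.Rational(1, 5), sympy.Rational(3, 10)]
        qs = sympy.zeros(4, 4)
        transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
        for i in range(4):
            for j in range(4):
                if i != j:
                    qs[i, j] = (kappa if (i, j) in transitions else 1) * f[j]
        for i in range(4):
            qs[i, i] = -sum(qs[i, j] for j in range(4) if j != i)
        mu = -sum(f[i] * qs[i, i] for i in range(4))
        qs = qs / mu
        q = hky_rate_matrix(2.0, [0.3, 0.2, 0.2, 0.3])
        assert np.allclose(q, np.array(qs, dtype=float), atol=1e-14)

    def test_invalid_frequencies(self):
        with pytest.raises(InvalidInputError):
            hky_rate_matrix(2.0, [0.5, 0.5, 0.2, -0.2])


class TestTransitionProbabilities:
    def test_identity_at_zero(self):
        q = hky_rate_matrix(3.0, [0.3, 0.2, 0.2, 0.3])
        assert np.allclose(transition_probabilities(q, 0.0), np.eye(4))

    def test_ergodic_limit(self):
        f = np.array([0.3, 0.2, 0.2, 0.3])
        q = hky_rate_matrix(3.0, f)
        p = transition_probabilities(q, 200.0)
        assert np.allclose(p, np.tile(f, (4, 1)), atol=1e-9)

    def test_jc_closed_form_diagonal(self):
        d = 0.1
        q = hky_rate_matrix(1.0, [0.25] * 4)
        p = transition_probabilities(q, d)
        assert np.allclose(np.diag(p), 0.25 + 0.75 * np.exp(-4 * d / 3))

    def test_rows_sum_to_one(self):
        q = hky_rate_matrix(7.0, [0.4, 0.1, 0.2, 0.3])
        p = transition_probabilities(q, 0.37)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-12)

    def test_negative_length_rejected(self):
        q = hky_rate_matrix(1.0, [0.25] * 4)
        with pytest.raises(InvalidInputError):
            transition_probabilities(q, -0.1)


class TestDiscreteGamma:
    def test_single_category(self):
        assert np.allclose(discrete_gamma_categories(0.3, 1), [1.0])

    @pytest.mark.parametrize("alpha", [0.1705, 0.5, 2.0, 10.0])
    def test_mean_exactly_one(self, alpha):
        rates = discrete_gamma_categories(alpha, 4)
        assert rates.mean() == pytest.approx(1.0, abs=1e-12)
        assert np.all(rates > 0)
        assert np.all(np.diff(rates) > 0)

    def test_quadrature_oracle_study_alpha(self):
        rates = discrete_gamma_categories(0.1705, 4)
        oracle = gamma_category_means_quadrature(0.1705, 4)
        assert np.allclose(rates, oracle, rtol=1e-6)

    def test_zero_categories_rejected(self):
        with pytest.raises(InvalidInputError):
            discrete_gamma_categories(0.5, 0)


class TestPruningLikelihood:
    def test_two_tip_hand_sum(self, two_tip_tree):
        sub = lb.SubstitutionModel.single_partition(kappa=1.0, gamma_alpha=1.0,
                                                    n_categories=1)
        rate = 2e-5
        aln = lb.Alignment(["a", "b"], ["A", "G"])
        ll = lb.tree_log_likelihood(aln, two_tip_tree, sub,
                                    lb.ClockModel(mean_rate=rate))
        q = hky_rate_matrix(1.0, [0.25] * 4)
        p = transition_probabilities(q, 5000 * rate)
        hand = sum(0.25 * p[x, 0] * p[x, 2] for x in range(4))
        assert ll == pytest.approx(np.log(hand), abs=1e-12)

    @pytest.mark.parametrize("n_tips,n_sites,seed", [
        (3, 2, 0), (4, 3, 1), (4, 4, 2), (5, 3, 3), (5, 4, 4),
    ])
    def test_enumeration_oracle(self, n_tips, n_sites, seed):
        rng = np.random.default_rng(seed)
        tree = lb.simulate_coalescent_tree(
            n_tips, lb.DemographicModel(theta0=1e4), rng)
        sub = lb.SubstitutionModel(
            kappa=[float(rng.uniform(1, 10)), float(rng.uniform(1, 10))],
            base_freqs=np.vstack([rng.dirichlet([8] * 4),
                                  rng.dirichlet([8] * 4)]),
            gamma_alpha=[float(rng.uniform(0.2, 2)),
                         float(rng.uniform(0.2, 2))],
            n_categories=4,
            rate_ratio=float(rng.uniform(0.5, 5)),
        )
        clock = lb.ClockModel(mean_rate=2e-5)
        aln = lb.simulate_alignment(tree, sub, clock, n_sites * 3, rng)
        aln = lb.Alignment.from_codes(aln.ids, aln.codes[:, : n_sites])
        sub1 = lb.SubstitutionModel.single_partition(
            kappa=sub.kappa[0], base_freqs=sub.base_freqs[0],
            gamma_alpha=sub.gamma_alpha[0])
        ll = lb.tree_log_likelihood(aln, tree, sub1, clock)
        oracle = enumeration_loglik(tree, aln, sub1, clock.mean_rate)
        assert ll == pytest.approx(oracle, abs=1e-10)

    def test_ambiguity_codes_partial_likelihood(self, two_tip_tree):
        sub = lb.SubstitutionModel.single_partition(kappa=1.0, gamma_alpha=1.0,
                                                    n_categories=1)
        clock = lb.ClockModel(mean_rate=2e-5)
        full = lb.Alignment(["a", "b"], ["N", "G"])
        ll = lb.tree_log_likelihood(full, two_tip_tree, sub, clock)
        # summing the tip-a likelihood over all states marginalizes to pi_G
        assert ll == pytest.approx(np.log(0.25), abs=1e-10)

    def test_label_mismatch(self, two_tip_tree):
        aln = lb.Alignment(["a", "zz"], ["A", "G"])
        with pytest.raises(InvalidInputError):
            lb.tree_log_likelihood(aln, two_tip_tree,
                                   lb.SubstitutionModel.single_partition(),
                                   lb.ClockModel())

    def test_rate_zero_constant_sites(self, two_tip_tree):
        # no substitutions: logL = sum_sites log pi(observed base)
        f = np.array([0.3, 0.2, 0.2, 0.3])
        sub = lb.SubstitutionModel.single_partition(base_freqs=f)
        aln = lb.Alignment(["a", "b"], ["AAC", "AAC"])
        ll = lb.tree_log_likelihood(aln, two_tip_tree, sub,
                                    lb.ClockModel(mean_rate=1e-30))
        assert ll == pytest.approx(2 * np.log(0.3) + np.log(0.2), abs=1e-6)

    def test_reroot_invariance_strict_clock(self, rng):
        """The likelihood of an ultrametric tree under reversible HKY is
        unchanged by which internal node carries the root, provided the tip
        path lengths are preserved (checked via equivalent representations
        of the same 3-tip tree)."""
        sub = lb.SubstitutionModel.single_partition(kappa=4.0,
                                                    base_freqs=[.3, .2, .2, .3],
                                                    gamma_alpha=0.7)
        clock = lb.ClockModel(mean_rate=2e-5)
        # ((a:1000,b:1000):2000,c:3000) vs (a:1000,(b? )) rotated labels
        t1 = lb.TimeTree.from_newick("((a:1000,b:1000):2000,c:3000);")
        t2 = lb.TimeTree.from_newick("(c:3000,(b:1000,a:1000):2000);")
        aln = lb.Alignment(["a", "b", "c"], ["ACGGT", "ACGTT", "GCGTA"])
        l1 = lb.tree_log_likelihood(aln, t1, sub, clock)
        l2 = lb.tree_log_likelihood(aln, t2, sub, clock)
        assert l1 == pytest.approx(l2, abs=1e-10)


class TestCoalescentDensity:
    def test_two_tip_exponential(self, two_tip_tree):
        n_ = 10_000.0
        d = lb.DemographicModel(theta0=n_)
        expected = np.log(1 / n_) - 5000.0 / n_
        assert coalescent_log_density(two_tip_tree, d) == pytest.approx(expected)

    def test_skyline_one_group_nests_constant(self, rng):
        for _ in range(5):
            tree = lb.simulate_coalescent_tree(
                7, lb.DemographicModel(theta0=2e4), rng)
            c = coalescent_log_density(tree, lb.DemographicModel(theta0=2e4))
            s = coalescent_log_density(
                tree, lb.DemographicModel(kind="skyline", group_sizes=[6],
                                          group_thetas=[2e4]))
            assert c == pytest.approx(s, abs=1e-10)

    def test_expansion_zero_growth_nests_constant(self, rng):
        tree = lb.simulate_coalescent_tree(6, lb.DemographicModel(theta0=1e4),
                                           rng)
        c = coalescent_log_density(tree, lb.DemographicModel(theta0=1e4))
        e = coalescent_log_density(
            tree, lb.DemographicModel(kind="expansion", theta0=1e4,
                                      growth_rate=0.0))
        assert c == pytest.approx(e, abs=1e-10)

    def test_expansion_matches_numerical_integral(self, rng):
        from scipy import integrate
        tree = lb.simulate_coalescent_tree(5, lb.DemographicModel(theta0=1e4),
                                           rng)
        d = lb.DemographicModel(kind="expansion", theta0=1e4,
                                growth_rate=3e-4, ancestral_fraction=0.05)
        times = tree.coalescent_times()
        logp = 0.0
        prev = 0.0
        for j, t in enumerate(times):
            k = 5 - j
            logp -= np.log(float(d.size_at(t)))
            integral, _ = integrate.quad(lambda s: 1.0 / float(d.size_at(s)),
                                         prev, t, limit=200)
            logp -= k * (k - 1) / 2 * integral
            prev = t
        assert coalescent_log_density(tree, d) == pytest.approx(logp, rel=1e-7)


class TestCalibrations:
    def test_outside_window_minus_inf(self, rng):
        tree = lb.simulate_coalescent_tree(
            4, lb.DemographicModel(theta0=3_000.0), rng,
            labels=["s1", "s2", "o1", "o2"])
        cal = CalibrationPrior(
            target="scand", taxa=("s1", "s2"), monophyly_enforced=False,
            density=TruncatedNormalCalibration(11_150.0, 1_000.0,
                                               9_200.0, 13_100.0))
        age = tree.ages[tree.mrca(["s1", "s2"])]
        lp = calibration_log_density(tree, [cal])
        if 9_200.0 <= age <= 13_100.0:
            assert np.isfinite(lp)
        else:
            assert lp == -np.inf

    def test_root_below_hard_minimum(self):
        tree = lb.TimeTree(np.array([2, 2, -1]),
                           np.array([0.0, 0.0, 14_000.0]), ["a", "b"])
        cal = CalibrationPrior(
            target="root", taxa=None,
            density=OffsetGammaCalibration(offset=14_685.0, peak=145_000.0))
        assert calibration_log_density(tree, [cal]) == -np.inf

    def test_truncated_normal_integrates_to_one(self):
        from scipy import integrate
        dens = TruncatedNormalCalibration(11_150.0, 1_000.0, 9_200.0, 13_100.0)
        val, _ = integrate.quad(lambda x: np.exp(dens.logpdf(x)),
                                9_200.0, 13_100.0, limit=200)
        assert val == pytest.approx(1.0, abs=1e-8)

    def test_offset_gamma_mode_at_peak(self):
        dens = OffsetGammaCalibration(offset=14_685.0, peak=145_000.0, shape=2.0)
        grid = np.linspace(14_700.0, 600_000.0, 20_000)
        assert grid[np.argmax(dens.logpdf(grid))] == pytest.approx(145_000.0,
                                                                   rel=1e-2)

    def test_offset_gamma_integrates_to_one(self):
        from scipy import integrate
        dens = OffsetGammaCalibration(offset=14_685.0, peak=24_000.0)
        val, _ = integrate.quad(lambda x: np.exp(dens.logpdf(x)),
                                14_685.0, np.inf, limit=400)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_monophyly_enforced(self, rng):
        # find a tree where a taxon pair is NOT monophyletic
        for seed in range(50):
            tree = lb.simulate_coalescent_tree(
                5, lb.DemographicModel(theta0=1e4), seed)
            if not tree.is_monophyletic(["t0", "t1"]):
                break
        cal = CalibrationPrior(
            target="x", taxa=("t0", "t1"), monophyly_enforced=True,
            density=TruncatedNormalCalibration(1e4, 1e4, 0.0, 1e9))
        assert calibration_log_density(tree, [cal]) == -np.inf


class TestUCLN:
    def test_sigma_zero_strict_equivalence(self):
        clock = lb.ClockModel(kind="ucln", mean_rate=1e-7, ucln_sigma=0.0,
                              branch_multipliers=np.ones(6))
        assert ucln_log_density(clock) == 0.0

    def test_matches_lognormal_pdf(self, rng):
        from scipy import stats
        sigma = 0.3
        m = rng.lognormal(-sigma**2 / 2, sigma, size=8)
        clock = lb.ClockModel(kind="ucln", mean_rate=1e-7, ucln_sigma=sigma,
                              branch_multipliers=m)
        expected = stats.lognorm.logpdf(m, s=sigma,
                                        scale=np.exp(-sigma**2 / 2)).sum()
        assert ucln_log_density(clock) == pytest.approx(expected, rel=1e-10)

    def test_mean_one_parameterization(self, rng):
        sigma = 0.5
        clock = lb.ClockModel(kind="ucln", mean_rate=1e-7, ucln_sigma=sigma)
        m = clock.multipliers_for(200_000, rng)
        se = m.std(ddof=1) / np.sqrt(len(m))
        assert abs(m.mean() - 1.0) < 3 * se

    def test_strict_clock_rejected(self):
        with pytest.raises(InvalidInputError):
            ucln_log_density(lb.ClockModel(kind="strict"))
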
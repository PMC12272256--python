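"""LD-chain genotype simulation and relative-pair generation."""

import numpy as np
import pytest
from scipy.stats import chisquare, norm

from deepkin import (
    LDChain,
    SimConfig,
    build_chain,
    compute_grm,
    dprime_to_d,
    genotypes_to_matrix,
    me_grm,
    sample_genotypes,
    sample_haplotypes,
    simulate_pair_single_locus,
    simulate_relative_pairs,
    single_locus_table,
    standardize,
    variance_validation,
)


class TestDprimeToD:
    def test_hand_arithmetic(self):
        assert dprime_to_d(0.3, 0.4, 0.5) == pytest.approx(0.09)

    def test_zero_dprime(self):
        assert dprime_to_d(0.2, 0.3, 0.0) == 0.0

    def test_perfect_ld_at_equal_frequencies(self):
        assert dprime_to_d(0.5, 0.5, 1.0) == pytest.approx(0.25)

    def test_negative_branch(self):
        assert dprime_to_d(0.3, 0.4, -0.5) == pytest.approx(-0.5 * 0.12)

    @pytest.mark.parametrize("dprime", [-1.0, -0.4, 0.0, 0.7, 1.0])
    def test_haplotype_frequencies_stay_nonnegative(self, dprime):
        for pA in (0.05, 0.3, 0.9):
            for pB in (0.1, 0.5, 0.95):
                d = dprime_to_d(pA, pB, dprime)
                haps = [
                    pA * pB + d,
                    pA * (1 - pB) - d,
                    (1 - pA) * pB - d,
                    (1 - pA) * (1 - pB) + d,
                ]
                assert min(haps) >= -1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            dprime_to_d(0.5, 0.5, 1.5)


class TestBuildChain:
    def test_conditional_probabilities(self):
        chain = LDChain(
            p=np.array([0.3, 0.4]),
            dprime=np.array([0.5]),
            d=np.array([0.09]),
        )
        p11, p10 = chain.conditional()
        assert p11[0] == pytest.approx((0.3 * 0.4 + 0.09) / 0.3)  # 0.7
        assert p10[0] == pytest.approx((0.7 * 0.4 - 0.09) / 0.7)

    def test_zero_d_gives_marginal(self):
        chain = LDChain(
            p=np.array([0.3, 0.4]), dprime=np.array([0.0]), d=np.array([0.0])
        )
        p11, p10 = chain.conditional()
        assert p11[0] == pytest.approx(0.4)
        assert p10[0] == pytest.approx(0.4)

    def test_transitions_always_valid(self, rng):
        for _ in range(20):
            chain = build_chain(50, (0.01, 0.5), (-1.0, 1.0), rng)
            p11, p10 = chain.conditional()
            assert np.all((p11 >= 0) & (p11 <= 1))
            assert np.all((p10 >= 0) & (p10 <= 1))

    def test_sampled_haplotypes_recover_dprime(self):
        chain = build_chain(20, (0.2, 0.4), (0.4, 0.6), seed=5)
        H = sample_haplotypes(chain, 100_000, seed=6).astype(float)
        pA, pB = H[:, :-1].mean(0), H[:, 1:].mean(0)
        d_obs = (H[:, :-1] * H[:, 1:]).mean(0) - pA * pB
        bound = np.minimum(pA * (1 - pB), (1 - pA) * pB)
        # Fisher-style check: each observed D' within 5 MC sigma of input
        se = np.sqrt(pA * (1 - pA) * pB * (1 - pB) / 100_000) / bound
        assert np.all(np.abs(d_obs / bound - chain.dprime) < 5 * se)


class TestSampleHaplotypes:
    def test_marginal_frequencies(self):
        chain = build_chain(100, seed=1)
        H = sample_haplotypes(chain, 50_000, seed=2)
        se = np.sqrt(chain.p * (1 - chain.p) / 50_000)
        assert np.all(np.abs(H.mean(0) - chain.p) < 5 * se)

    def test_independence_without_ld(self):
        chain = build_chain(200, dprime_dist=(0.0, 0.0), seed=3)
        H = sample_haplotypes(chain, 5_000, seed=4).astype(float)
        r = [
            np.corrcoef(H[:, l], H[:, l + 1])[0, 1] ** 2
            for l in range(199)
        ]
        # adjacent r^2 at the 1/count noise scale
        assert np.mean(r) < 5 / 5_000

    def test_seed_reproducibility(self):
        chain = build_chain(30, seed=8)
        a = sample_haplotypes(chain, 100, seed=9)
        b = sample_haplotypes(chain, 100, seed=9)
        assert np.array_equal(a, b)


class TestSingleLocusPairs:
    def test_full_relatedness_copies_genotypes(self):
        gi, gj = simulate_pair_single_locus(1.0, 0.4, 500, m=3, seed=0)
        assert np.array_equal(gi, gj)

    def test_unrelated_pairs_independent(self):
        gi, gj = simulate_pair_single_locus(0.0, 0.5, 200_000, seed=1)
        r = np.corrcoef(gi[:, 0], gj[:, 0])[0, 1]
        assert abs(r) < 5 / np.sqrt(200_000)

    def test_duplicate_class_frequency(self):
        # P{2,2} = [theta p + (1-theta) p^2]^2 = 0.140625 at theta=p=0.5
        gi, gj = simulate_pair_single_locus(0.5, 0.5, 100_000, seed=2)
        freq = np.mean((gi[:, 0] == 2) & (gj[:, 0] == 2))
        expected = 0.140625
        se = np.sqrt(expected * (1 - expected) / 100_000)
        assert abs(freq - expected) < 4 * se

    @pytest.mark.parametrize("theta", [0.0, 0.125, 0.25, 0.5])
    @pytest.mark.parametrize("p", [0.1, 0.3, 0.5])
    def test_six_class_goodness_of_fit(self, theta, p):
        """Empirical genotype-pair class counts match the analytic
        probabilities (chi-square GOF p > 0.01) on a (theta, p) grid."""
        n = 100_000
        gi, gj = simulate_pair_single_locus(theta, p, n, seed=37)
        f, _ = single_locus_table(theta, p)
        classes = [(2, 2), (1, 1), (0, 0), (2, 1), (1, 0), (2, 0)]
        counts = np.zeros(6)
        for k, (a, b) in enumerate(classes):
            counts[k] = np.sum(
                ((gi[:, 0] == a) & (gj[:, 0] == b))
                | ((gi[:, 0] == b) & (gj[:, 0] == a))
            )
        keep = f * n >= 5
        stat, pval = chisquare(counts[keep], f[keep] / f[keep].sum() * counts[keep].sum())
        assert pval > 0.01


class TestRelativePairs:
    def test_zero_theta_gives_independent_cohorts(self):
        chain = build_chain(300, seed=21)
        gi, gj = simulate_relative_pairs(0.0, chain, 3_000, seed=22)
        from deepkin.sim import _pair_thetas_from_genotypes

        thetas = _pair_thetas_from_genotypes(gi, gj)
        se = thetas.std(ddof=1) / np.sqrt(len(thetas))
        assert abs(thetas.mean()) < 4 * se

    @pytest.mark.parametrize("theta", [0.125, 0.25, 0.5])
    def test_unbiasedness(self, theta):
        chain = build_chain(5_000, seed=31)
        gi, gj = simulate_relative_pairs(theta, chain, 2_000, seed=32)
        from deepkin.sim import _pair_thetas_from_genotypes

        thetas = _pair_thetas_from_genotypes(gi, gj)
        se = thetas.std(ddof=1) / np.sqrt(len(thetas))
        assert abs(thetas.mean() - theta) < 3 * se

    def test_marginal_frequency_preserved(self):
        chain = build_chain(400, seed=41)
        _, gj = simulate_relative_pairs(0.5, chain, 5_000, seed=42)
        se = np.sqrt(chain.p * (1 - chain.p) / (2 * 5_000))
        assert np.all(np.abs(gj.mean(0) / 2 - chain.p) < 5 * se)


class TestVarianceValidation:
    def test_perfect_relatedness_has_zero_observed_variance(self):
        table = variance_validation(
            [SimConfig(theta=1.0, n_pairs=200, m=50, model="single", seed=1)],
            repeats=3,
        )
        assert table["observed_var"].iloc[0] == pytest.approx(0.0, abs=1e-20)

    def test_single_locus_scenario_consistent(self):
        table = variance_validation(
            [
                SimConfig(
                    theta=0.0, n_pairs=1_000, m=500, model="single",
                    maf=0.25, seed=2,
                )
            ],
            repeats=5,
        )
        row = table.iloc[0]
        # expected = [0.5 + 1/(4 * 0.1875)] / m
        assert row["expected_var"] == pytest.approx(
            (0.5 + 1 / 0.75) / 500, rel=1e-12
        )
        assert row["consistent"]

    def test_multi_low_ld_unrelated_ratio_near_one(self):
        table = variance_validation(
            [
                SimConfig(
                    theta=0.0, n_pairs=2_000, m=1_000, model="multi", seed=3
                )
            ],
            repeats=6,
        )
        row = table.iloc[0]
        assert 0.9 < row["observed_var"] / row["expected_var"] < 1.1

    def test_multi_related_variance_follows_binomial_expectation(self):
        """Allele-sharing relatives have the exact binomial per-locus
        variance; the Gaussian asymptotic 2(1-theta)^2/me understates it
        increasingly with theta (genotype kurtosis at theta = 0.5 roughly
        doubles the variance under MAF ~ U(0.05, 0.5))."""
        table = variance_validation(
            [
                SimConfig(
                    theta=0.5, n_pairs=1_000, m=500, model="multi", seed=4
                )
            ],
            repeats=10,
        )
        row = table.iloc[0]
        assert 0.8 < row["observed_var"] / row["expected_var_binomial"] < 1.1
        assert row["observed_var"] / row["expected_var"] > 1.4
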
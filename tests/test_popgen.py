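"""Population statistics: discovery curve, homozygosity test, overlap
permutation, heritability."""

import numpy as np
import pytest
from scipy import stats

from methylseg.popgen import (
    BetaPrior,
    HaplotypeReadCounts,
    beta_prior_moments,
    classify_variant,
    discovery_curve,
    estimate_total_sites,
    fit_beta_prior,
    heritability_lmm,
    homozygosity_calls,
    homozygosity_pvalue,
    kinship_matrix,
    mutant_gain_loss,
    overlap_permutation_z,
)
from methylseg.simulate import simulate_genotypes, simulate_phenotype


class TestBetaPrior:
    def test_uniform_prior_moments(self):
        mean, sd = beta_prior_moments(BetaPrior(1.0, 1.0))
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(np.sqrt(1 / 12))

    def test_moments_match_scipy_for_random_parameters(self, rng):
        for _ in range(20):
            a, b = rng.uniform(0.05, 8, size=2)
            mean, sd = beta_prior_moments(BetaPrior(a, b))
            assert mean == pytest.approx(stats.beta.mean(a, b), rel=1e-12)
            assert sd == pytest.approx(stats.beta.std(a, b), rel=1e-12)

    def test_fit_recovers_generating_parameters(self, rng):
        a, b, n = 0.029, 0.644, 13
        f = rng.beta(a, b, size=100_000)
        k = rng.binomial(n, f)
        sfs = np.bincount(k, minlength=n + 1)
        fit = fit_beta_prior(sfs, n)
        assert fit.a == pytest.approx(a, rel=0.2)
        assert fit.b == pytest.approx(b, rel=0.2)

    def test_symmetric_spectrum_gives_symmetric_fit(self, rng):
        n = 10
        f = rng.beta(2.0, 2.0, size=50_000)
        k = rng.binomial(n, f)
        sfs = np.bincount(k, minlength=n + 1)
        fit = fit_beta_prior(sfs, n)
        assert fit.a == pytest.approx(fit.b, rel=0.1)

    def test_fit_likelihood_beats_truth(self, rng):
        from scipy.special import betaln, gammaln

        a, b, n = 0.5, 2.0, 8
        f = rng.beta(a, b, size=20_000)
        k = rng.binomial(n, f)
        sfs = np.bincount(k, minlength=n + 1)
        fit = fit_beta_prior(sfs, n)

        def ll(aa, bb):
            kk = np.arange(n + 1.0)
            lch = gammaln(n + 1) - gammaln(kk + 1) - gammaln(n - kk + 1)
            return float(np.sum(sfs * (lch + betaln(kk + aa, n - kk + bb)
                                       - betaln(aa, bb))))

        assert ll(fit.a, fit.b) >= ll(a, b) - 1e-6

    def test_all_zero_spectrum_rejected(self):
        with pytest.raises(ValueError):
            fit_beta_prior(np.zeros(14), 13)


class TestDiscoveryCurve:
    PRIOR = BetaPrior(0.029, 0.644)

    def test_zero_samples_discover_nothing(self):
        curve = discovery_curve(self.PRIOR, 1e6)
        assert curve(0) == 0.0

    def test_monotone_and_bounded(self):
        curve = discovery_curve(self.PRIOR, 1e6)
        vals = [curve(n) for n in range(0, 200, 5)]
        assert all(b >= a for a, b in zip(vals, vals[1:]))
        assert curve(10_000) <= 1e6

    def test_saturates_to_total_for_well_behaved_prior(self):
        # saturation to N * P(f > 0) = N; fast for a moderate prior
        curve = discovery_curve(BetaPrior(2.0, 2.0), 1e6)
        assert curve(10_000) / 1e6 > 0.999

    def test_matches_monte_carlo(self, rng):
        curve = discovery_curve(self.PRIOR, 1.0)
        f = rng.beta(self.PRIOR.a, self.PRIOR.b, size=1_000_000)
        for n in (1, 13, 140):
            mc = 1.0 - np.mean((1.0 - f) ** n)
            assert curve(n) == pytest.approx(mc, rel=0.005)

    def test_total_sites_inversion_round_trips(self):
        curve = discovery_curve(self.PRIOR, 5e5)
        d13 = curve(13)
        assert estimate_total_sites(self.PRIOR, d13, 13) == pytest.approx(5e5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            discovery_curve(self.PRIOR, 0)
        with pytest.raises(ValueError):
            discovery_curve(self.PRIOR, 10).delta(-1)


class TestHomozygosityTest:
    def test_pure_branch_consistent_with_null(self):
        p = homozygosity_pvalue(HaplotypeReadCounts(20, 0), af_null=0.95)
        assert p == pytest.approx(1.0)

    def test_balanced_counts_exact_tail(self):
        # P(X <= 10 | Binom(20, 0.95)) by direct summation
        expected = sum(
            stats.binom.pmf(k, 20, 0.95) for k in range(11)
        )
        p = homozygosity_pvalue(HaplotypeReadCounts(10, 10))
        assert p == pytest.approx(expected, rel=1e-10)
        assert p < 1e-6

    def test_low_coverage_marked_missing(self):
        calls = homozygosity_calls([HaplotypeReadCounts(1, 1)])
        assert calls == ["missing"]

    def test_call_sides(self):
        counts = [HaplotypeReadCounts(20, 0), HaplotypeReadCounts(0, 20),
                  HaplotypeReadCounts(10, 10)] * 40
        calls = homozygosity_calls(counts)
        assert calls[0] == "present-branch"
        assert calls[1] == "present-reference"
        assert calls[2] == "ambiguous"


class TestVariantClassification:
    def test_branch_everywhere_is_common(self):
        calls = ["present-branch"] * 13
        counts = [HaplotypeReadCounts(10, 0)] * 13
        assert classify_variant(calls, counts) == "common"

    def test_mixed_support_is_segregating(self):
        calls = ["present-branch"] * 6 + ["present-reference"] * 7
        counts = [HaplotypeReadCounts(10, 0)] * 6 + [HaplotypeReadCounts(0, 10)] * 7
        assert classify_variant(calls, counts) == "segregating"

    def test_too_few_informative_strains(self):
        calls = ["present-branch"] * 6 + ["missing"] * 7
        counts = [HaplotypeReadCounts(10, 0)] * 6 + [HaplotypeReadCounts(1, 0)] * 7
        assert classify_variant(calls, counts) == "insufficient"

    def test_two_fold_rescue_applies(self):
        calls = ["present-branch"] * 12 + ["ambiguous"]
        counts = [HaplotypeReadCounts(10, 0)] * 12 + [HaplotypeReadCounts(8, 4)]
        assert classify_variant(calls, counts) == "common"


class TestMutantGainLoss:
    @pytest.mark.parametrize(
        "wt1,wt2,mut,expected",
        [
            (0.5, 0.3, 0.05, "lost"),
            (0.05, 0.15, 0.4, "gained"),
            (0.12, 0.15, 0.5, "unchanged"),  # WT not methylated (neither > 20%)
            (0.5, 0.3, 0.5, "unchanged"),
            (0.5, 0.3, float("nan"), "not-assessable"),
        ],
    )
    def test_rule_application(self, wt1, wt2, mut, expected):
        assert mutant_gain_loss(wt1, wt2, mut) == expected

    def test_rates_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError):
            mutant_gain_loss(1.2, 0.5, 0.5)


class TestOverlapPermutation:
    UNIVERSE = [("chr1", 1, 2000), ("chr2", 1, 1000)]

    def test_self_overlap_is_total_and_enriched(self, rng):
        regions = [("chr1", int(s), int(s) + 20) for s in range(100, 900, 100)]
        obs, z, p = overlap_permutation_z(regions, regions, self.UNIVERSE,
                                          n_perm=200, rng=rng)
        assert obs == len(regions)
        assert z > 3
        assert p < 0.05

    def test_independent_sets_give_small_z(self, rng):
        a = [("chr1", int(s), int(s) + 5) for s in rng.integers(1, 1900, 8)]
        b = [("chr2", int(s), int(s) + 5) for s in rng.integers(1, 900, 8)]
        obs, z, p = overlap_permutation_z(a, b, self.UNIVERSE, n_perm=200, rng=rng)
        assert obs == 0
        assert abs(z) < 3

    def test_order_invariance(self):
        a = [("chr1", 100, 150), ("chr1", 500, 540), ("chr2", 10, 60)]
        b = [("chr1", 120, 130), ("chr2", 700, 720)]
        r1 = overlap_permutation_z(a, b, self.UNIVERSE, n_perm=50,
                                   rng=np.random.default_rng(3))
        r2 = overlap_permutation_z(a[::-1], b[::-1], self.UNIVERSE, n_perm=50,
                                   rng=np.random.default_rng(3))
        assert r1 == r2

    def test_permutation_mean_matches_occupancy_formula(self, rng):
        # 1-bp regions in a single segment of length L: the chance one
        # a-region hits >= 1 of n_b b-regions is 1 - (1 - 1/L)^n_b
        L, n_a, n_b = 50, 6, 8
        universe = [("chr1", 1, L)]
        a = [("chr1", i + 1, i + 1) for i in range(n_a)]
        b = [("chr1", i + 10, i + 10) for i in range(n_b)]
        _, _, _ = overlap_permutation_z(a, b, universe, n_perm=10, rng=rng)
        null = []
        from methylseg.popgen import _count_overlaps, _place_regions

        for _ in range(4000):
            pa = _place_regions([1] * n_a, universe, rng)
            pb = _place_regions([1] * n_b, universe, rng)
            null.append(_count_overlaps(pa, pb))
        expected = n_a * (1.0 - (1.0 - 1.0 / L) ** n_b)
        assert np.mean(null) == pytest.approx(expected, rel=0.05)

    def test_oversized_region_rejected(self, rng):
        with pytest.raises(ValueError):
            overlap_permutation_z([("chr1", 1, 5000)], [], self.UNIVERSE,
                                  n_perm=5, rng=rng)


class TestGenotypeInput:
    def test_vcf_reader_codes_haploid_calls(self, tmp_path):
        from methylseg.popgen import read_genotype_matrix

        vcf = tmp_path / "g.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            "##contig=<ID=chr1,length=1000>\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
            "chr1\t100\t.\tA\tT\t50\tPASS\t.\tGT\t0/0\t1/1\t0/1\n"
            "chr1\t200\t.\tG\tC\t50\tPASS\t.\tGT\t1/1\t0/0\t1/1\n"
        )
        df = read_genotype_matrix(vcf, format="vcf")
        assert list(df.index) == ["S1", "S2", "S3"]
        assert df.loc["S1", "chr1:100"] == 0
        assert df.loc["S2", "chr1:100"] == 1
        assert np.isnan(df.loc["S3", "chr1:100"])  # heterozygous-like

    def test_tsv_round_trip(self, tmp_path):
        import pandas as pd
        from methylseg.popgen import read_genotype_matrix

        df = pd.DataFrame([[0, 1], [1, 0]], index=["A", "B"],
                          columns=["v1", "v2"])
        path = tmp_path / "g.tsv"
        df.to_csv(path, sep="\t")
        back = read_genotype_matrix(path)
        pd.testing.assert_frame_equal(df, back)


class TestHeritability:
    def test_kinship_diagonal_near_one(self, rng):
        G = simulate_genotypes(50, 400, rng)
        K = kinship_matrix(G)
        assert np.allclose(K, K.T)
        assert np.mean(np.diag(K)) == pytest.approx(1.0, abs=0.1)

    def test_pure_noise_phenotype_has_low_h2(self, rng):
        G = simulate_genotypes(120, 500, rng)
        K = kinship_matrix(G)
        ests = [
            heritability_lmm(rng.standard_normal(120), K).h2 for _ in range(10)
        ]
        assert np.median(ests) < 0.2

    def test_phenotype_on_genotype_pc_saturates_h2(self, rng):
        G = simulate_genotypes(100, 400, rng)
        K = kinship_matrix(G)
        S, U = np.linalg.eigh(K)
        y = U[:, -1]  # exact linear function of the leading genotype PC
        est = heritability_lmm(y, K)
        assert est.h2 > 0.95

    def test_estimates_bounded_and_se_finite(self, rng):
        G = simulate_genotypes(60, 200, rng)
        K = kinship_matrix(G)
        for h2 in (0.2, 0.5, 0.8):
            y = simulate_phenotype(K, h2=h2, rng=rng)
            est = heritability_lmm(y, K)
            assert 0.0 <= est.h2 <= 1.0
            assert est.se >= 0

    def test_permuted_phenotype_destroys_heritability(self, rng):
        G = simulate_genotypes(120, 500, rng)
        K = kinship_matrix(G)
        y = simulate_phenotype(K, h2=0.8, rng=rng)
        perms = [
            heritability_lmm(rng.permutation(y), K).h2 for _ in range(15)
        ]
        assert np.median(perms) < 0.1

    def test_input_validation(self, rng):
        with pytest.raises(ValueError):
            heritability_lmm([1.0, 2.0], np.eye(2))
        with pytest.raises(ValueError):
            heritability_lmm(np.ones(4), -np.eye(4))
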
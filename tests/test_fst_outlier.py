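"""Population-genetic machinery: counts, F_ST, HWE, LD, the outlier scan."""

import dataclasses
import math

import numpy as np
import pytest
from scipy.special import gammaln
from scipy.stats import kstest

import altisel as al
from altisel.fst_outlier import (
    AlleleCountTable,
    GenotypeMatrix,
    LdSettings,
    McmcSettings,
    OutlierResult,
    allele_counts_from_genotypes,
    bayescan_scan,
    classify_outliers,
    hwe_exact,
    ld_test,
    qvalues_from_posterior,
    transect_consistency,
    wc_fst,
)

SHORT_CHAIN = McmcSettings(
    n_iter=7000, burn_in=5000, thinning=1, n_pilot=5, pilot_length=500, seed=0
)


class TestAlleleCounts:
    def test_two_individuals(self):
        g = GenotypeMatrix(
            ["l1"], ["i1", "i2"], ["p1", "p1"], np.array([[0, 2]])
        )
        counts = allele_counts_from_genotypes(g)
        assert counts.alt_counts[0, 0] == 2
        assert counts.totals[0, 0] == 4

    def test_all_missing_population_flagged(self):
        g = GenotypeMatrix(
            ["l1"], ["i1", "i2"], ["p1", "p2"], np.array([[-1, 1]])
        )
        counts = allele_counts_from_genotypes(g)
        assert counts.totals[0, 0] == 0
        assert counts.flagged_loci == ["l1"]

    def test_matches_brute_force_tally(self):
        rng = np.random.default_rng(3)
        pops = ["p1"] * 6 + ["p2"] * 5 + ["p3"] * 4
        geno = rng.choice([-1, 0, 1, 2], size=(12, 15), p=[0.1, 0.3, 0.3, 0.3])
        g = GenotypeMatrix(
            [f"l{i}" for i in range(12)],
            [f"i{j}" for j in range(15)],
            pops,
            geno,
        )
        counts = allele_counts_from_genotypes(g)
        for i in range(12):
            for j, pop in enumerate(counts.populations):
                idx = [k for k, p in enumerate(pops) if p == pop]
                vals = [geno[i, k] for k in idx if geno[i, k] >= 0]
                assert counts.alt_counts[i, j] == sum(vals)
                assert counts.totals[i, j] == 2 * len(vals)


class TestWcFst:
    def test_identical_frequencies_near_zero(self):
        params = al.IslandModelParams(
            n_pops=4, n_loci=300, beta=-8.0, sample_sizes=200, seed=1
        )
        counts, _ = al.simulate_allele_counts(params)
        assert abs(wc_fst(counts)["global_fst"]) < 0.02

    def test_fixed_alternative_alleles_give_one(self):
        counts = AlleleCountTable(
            ["l1"], ["p1", "p2"], np.array([[0, 20]]), np.array([[20, 20]])
        )
        assert wc_fst(counts)["per_locus_fst"][0] == pytest.approx(1.0)

    def test_worksheet_values(self):
        # a = (5, 15), n = (20, 20): p = (0.25, 0.75), pbar = 0.5, nc = 20,
        # MSP = 20*(0.25^2)*2 / 1 = 2.5, MSG = (2*20*0.1875)/38 = 0.197368,
        # theta = (MSP-MSG)/(MSP+19*MSG) = 2.302632/6.25 = 0.3684211
        counts = AlleleCountTable(
            ["l1"], ["p1", "p2"], np.array([[5, 15]]), np.array([[20, 20]])
        )
        got = wc_fst(counts)
        assert got["per_locus_fst"][0] == pytest.approx(0.3684211, abs=1e-6)
        assert got["global_fst"] == pytest.approx(0.3684211, abs=1e-6)

    def test_monomorphic_locus_is_missing(self):
        counts = AlleleCountTable(
            ["l1", "l2"],
            ["p1", "p2"],
            np.array([[0, 0], [5, 15]]),
            np.array([[20, 20], [20, 20]]),
        )
        per_locus = wc_fst(counts)["per_locus_fst"]
        assert math.isnan(per_locus[0])
        assert not math.isnan(per_locus[1])

    def test_invariant_to_allele_label_swap(self):
        rng = np.random.default_rng(4)
        n = np.full((20, 3), 40)
        a = rng.integers(0, 41, size=(20, 3))
        c1 = AlleleCountTable([f"l{i}" for i in range(20)], ["a", "b", "c"], a, n)
        c2 = AlleleCountTable([f"l{i}" for i in range(20)], ["a", "b", "c"], n - a, n)
        np.testing.assert_allclose(
            wc_fst(c1)["per_locus_fst"], wc_fst(c2)["per_locus_fst"],
            equal_nan=True,
        )


def hwe_enumeration_oracle(n_aa, n_het, n_bb):
    """Levene-Haldane conditional test by explicit table enumeration."""
    n = n_aa + n_het + n_bb
    n_a = 2 * n_aa + n_het
    if n_a == 0 or n_a == 2 * n:
        return 1.0

    def log_prob(h):
        aa = (n_a - h) // 2
        bb = (2 * n - n_a - h) // 2
        return (
            gammaln(n + 1) - gammaln(aa + 1) - gammaln(h + 1) - gammaln(bb + 1)
            + h * math.log(2)
            + gammaln(n_a + 1) + gammaln(2 * n - n_a + 1) - gammaln(2 * n + 1)
        )
    hs = [h for h in range(n_a % 2, min(n_a, 2 * n - n_a) + 1, 2)]
    logps = np.array([log_prob(h) for h in hs])
    probs = np.exp(logps - logps.max())
    probs = probs / probs.sum()
    observed = probs[hs.index(n_het)]
    return float(min(1.0, probs[probs <= observed * (1 + 1e-12)].sum()))


class TestHweExact:
    def test_monomorphic_gives_one(self):
        assert hwe_exact(5, 0, 0) == 1.0

    def test_two_heterozygotes_enumeration(self):
        # alleles 2 A, 2 a over 2 diploids: tables are h in {0, 2} with
        # P(h=2) = 2/3, P(h=0) = 1/3; observed h=2 -> p = 1
        assert hwe_exact(0, 2, 0) == pytest.approx(1.0)
        assert hwe_exact(1, 0, 1) == pytest.approx(1 / 3)

    def test_random_tables_match_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(60):
            n_aa, n_het, n_bb = rng.integers(0, 11, size=3)
            if n_aa + n_het + n_bb == 0:
                continue
            got = hwe_exact(int(n_aa), int(n_het), int(n_bb))
            want = hwe_enumeration_oracle(int(n_aa), int(n_het), int(n_bb))
            assert got == pytest.approx(want, abs=1e-12)

    def test_mc_mode_approximates_exact(self):
        exact = hwe_exact(10, 5, 10)
        mc = hwe_exact(
            10, 5, 10, method="mc", mc_steps=200_000, dememorization=2_000,
            seed=1,
        )
        assert mc == pytest.approx(exact, abs=0.02)

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            hwe_exact(-1, 0, 1)
        with pytest.raises(ValueError):
            hwe_exact(0, 0, 0)


class TestLdTest:
    SETTINGS = LdSettings(dememorization=500, n_batches=20, batch_length=250, seed=0)

    def test_monomorphic_partner_gives_one(self):
        ga = np.zeros(30, dtype=int)
        gb = np.tile([0, 1, 2], 10)
        p, se = ld_test(ga, gb, self.SETTINGS)
        assert p == 1.0 and se == 0.0

    def test_duplicated_locus_strongly_linked(self):
        rng = np.random.default_rng(2)
        g = rng.choice([0, 1, 2], size=40, p=[0.25, 0.5, 0.25])
        p, se = ld_test(g, g.copy(), self.SETTINGS)
        assert p < 0.01

    def test_independent_loci_p_roughly_uniform(self):
        rng = np.random.default_rng(11)
        ps = []
        for trial in range(200):
            ga = rng.choice([0, 1, 2], size=40, p=[0.25, 0.5, 0.25])
            gb = rng.choice([0, 1, 2], size=40, p=[0.25, 0.5, 0.25])
            settings = LdSettings(
                dememorization=300, n_batches=10, batch_length=150, seed=trial
            )
            ps.append(ld_test(ga, gb, settings)[0])
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="same individuals"):
            ld_test(np.zeros(5), np.zeros(6))


class TestQvalues:
    def test_all_certain_gives_zero(self):
        np.testing.assert_allclose(qvalues_from_posterior([1.0, 1.0]), 0.0)

    def test_cumulative_mean_arithmetic(self):
        np.testing.assert_allclose(
            qvalues_from_posterior([0.9, 0.5]), [0.1, 0.3]
        )

    def test_all_zero_gives_one(self):
        np.testing.assert_allclose(qvalues_from_posterior([0.0, 0.0, 0.0]), 1.0)

    def test_order_independence(self):
        p = [0.2, 0.9, 0.6, 0.1]
        q = qvalues_from_posterior(p)
        q_rev = qvalues_from_posterior(p[::-1])
        np.testing.assert_allclose(q, q_rev[::-1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            qvalues_from_posterior([1.2])


class TestClassify:
    def _result(self, q, alpha):
        return OutlierResult("l", alpha, 0.1, 0.9, q, 0.2)

    def test_diversifying(self):
        out = classify_outliers([self._result(0.01, 1.2)])
        assert out[0].selection_class == "diversifying"

    def test_balancing(self):
        out = classify_outliers([self._result(0.01, -0.8)])
        assert out[0].selection_class == "balancing"

    def test_neutral_above_threshold(self):
        out = classify_outliers([self._result(0.20, 5.0)])
        assert out[0].selection_class == "neutral"


class TestTransectConsistency:
    def _res(self, locus, cls):
        return OutlierResult(locus, 1.0 if cls == "diversifying" else -1.0,
                             0.1, 0.9, 0.01 if cls != "neutral" else 0.5,
                             0.3, selection_class=cls)

    def test_consistent_locus_reported(self):
        g = [self._res("l1", "balancing"), self._res("l2", "neutral")]
        t1 = [self._res("l1", "balancing"), self._res("l2", "diversifying")]
        t2 = [self._res("l1", "balancing"), self._res("l2", "neutral")]
        df = transect_consistency(g, [t1, t2])
        assert list(df["locus_id"]) == ["l1"]
        assert bool(df["class_agreement"][0])

    def test_global_only_locus_excluded(self):
        g = [self._res("l1", "diversifying")]
        t1 = [self._res("l1", "neutral")]
        assert transect_consistency(g, [t1]).empty

    def test_empty_outlier_sets(self):
        g = [self._res("l1", "neutral")]
        t1 = [self._res("l1", "neutral")]
        assert transect_consistency(g, [t1]).empty


class TestBayescanScan:
    def test_seed_reproducibility(self):
        params = al.IslandModelParams(n_pops=4, n_loci=30, seed=3)
        counts, _ = al.simulate_allele_counts(params)
        settings = dataclasses.replace(
            SHORT_CHAIN, n_iter=2000, burn_in=1000, n_pilot=2, pilot_length=200
        )
        s1 = bayescan_scan(counts, settings)
        s2 = bayescan_scan(counts, settings)
        for r1, r2 in zip(s1.results, s2.results):
            assert r1.alpha_mean == r2.alpha_mean
            assert r1.inclusion_prob == r2.inclusion_prob
            assert r1.q_value == r2.q_value

    def test_monomorphic_loci_excluded(self):
        a = np.array([[0, 0, 0], [5, 10, 15], [3, 6, 9]])
        n = np.full((3, 3), 20)
        counts = AlleleCountTable(["m", "x", "y"], ["p1", "p2", "p3"], a, n)
        settings = dataclasses.replace(
            SHORT_CHAIN, n_iter=1000, burn_in=500, n_pilot=1, pilot_length=100
        )
        scan = bayescan_scan(counts, settings)
        assert scan.excluded_monomorphic == ["m"]
        assert {r.locus_id for r in scan.results} == {"x", "y"}

    def test_too_few_populations_rejected(self):
        counts = AlleleCountTable(
            ["l1", "l2"], ["p1"], np.array([[1], [2]]), np.array([[10], [10]])
        )
        with pytest.raises(ValueError, match="populations"):
            bayescan_scan(counts, SHORT_CHAIN)

    def test_conditional_alpha_matches_grid_posterior(self):
        # one strongly selected locus among neutral loci, two populations;
        # with beta pinned by the neutral loci, the chain's conditional
        # alpha posterior should match a dense-grid posterior over
        # (alpha, p) computed by numerical integration
        rng = np.random.default_rng(1)
        n_loci = 25
        alpha = np.zeros(n_loci)
        alpha[0] = 1.5
        params = al.IslandModelParams(
            n_pops=2, n_loci=n_loci, beta=-1.0, alpha=alpha,
            sample_sizes=400, seed=9,
        )
        counts, _ = al.simulate_allele_counts(params)
        settings = dataclasses.replace(
            SHORT_CHAIN,
            n_iter=12_000, burn_in=4_000, prior_odds_neutral=0.05, seed=2,
        )
        scan = bayescan_scan(counts, settings)
        target = scan.results[0]
        assert target.inclusion_prob > 0.5  # conditional mean is meaningful

        # dense-grid posterior of alpha for locus 0, beta at its posterior mean
        from scipy.integrate import simpson
        from scipy.special import betaln, expit

        beta = scan.beta_mean
        a_row = counts.alt_counts[0].astype(float)
        n_row = counts.totals[0].astype(float)
        ag = np.linspace(-4, 5, 301)
        pg = np.linspace(0.002, 0.998, 249)

        def loglik(alpha_i, p_i):
            f = expit(alpha_i + beta)
            theta = 1 / f - 1
            s1, s2 = p_i * theta, (1 - p_i) * theta
            return (
                betaln(a_row + s1, n_row - a_row + s2) - betaln(s1, s2)
            ).sum()

        grid = np.array([[loglik(a, p) for p in pg] for a in ag])
        grid += -0.5 * ag[:, None] ** 2  # N(0,1) prior on alpha
        w = np.exp(grid - grid.max())
        marginal = simpson(w, x=pg, axis=1)
        post_mean = simpson(ag * marginal, x=ag) / simpson(marginal, x=ag)
        assert target.alpha_mean == pytest.approx(post_mean, abs=0.1)


class TestGenotypeMatrixContainer:
    def test_population_subset(self):
        g = al.simulate_genotypes(np.full((5, 3), 0.5), n_ind=4, seed=0)
        sub = g.subset_populations(["pop1", "pop3"])
        assert set(sub.populations) == {"pop1", "pop3"}
        assert sub.genotypes.shape == (5, 8)

    def test_genotype_counts(self):
        g = GenotypeMatrix(
            ["l1"], ["a", "b", "c"], ["p1", "p1", "p2"],
            np.array([[0, 1, 2]]),
        )
        assert g.genotype_counts(0, "p1") == (1, 1, 0)
        assert g.genotype_counts(0, "p2") == (0, 0, 1)

    def test_tsv_roundtrip(self, tmp_path):
        params = al.IslandModelParams(n_pops=3, n_loci=8, seed=4)
        counts, _ = al.simulate_allele_counts(params)
        path = tmp_path / "counts.tsv"
        counts.to_tsv(path, header_comment="demo")
        back = AlleleCountTable.from_tsv(path)
        np.testing.assert_array_equal(back.alt_counts, counts.alt_counts)
        np.testing.assert_array_equal(back.totals, counts.totals)
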
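"""GY94 machinery: rate matrix, pruning likelihood, fits, LRT."""

import numpy as np
import pytest
from scipy.linalg import expm
from scipy.stats import chi2

import altisel as al
from altisel._codons import GAP_STATE, IS_SYNONYMOUS, N_SENSE, ONE_DIFF
from altisel.alignment import CodonAlignment
from altisel.codon_ml import (
    CodonModelParams,
    SiteClassMix,
    build_rate_matrix,
    f3x4_frequencies,
    fit_branch,
    fit_m0,
    log_likelihood,
    lrt,
)
from tests.conftest import random_codon_seq


def enumeration_lnl(aln, tree, pi, kappa, omega_map, scale_factor=None):
    """Independent likelihood oracle: explicit sum over internal states.

    Transition matrices come from scipy's expm (not the eigendecomposition
    the pruning engine uses), and the site likelihood marginalises the
    internal-node codon assignments by direct summation.
    """
    enc = aln.encode()
    row_of = {t: aln.taxon_ids.index(t) for t in tree.taxa}
    p_mats = {
        b: expm(build_rate_matrix(pi, omega_map[b], kappa, scale_factor) * t)
        for b, t in tree.branch_lengths.items()
    }
    internals = [n for n in tree.postorder if not n.is_leaf]

    # postorder puts the root last; its state is the vectorised axis,
    # every other internal node is enumerated explicitly
    assert internals[-1] is tree.root
    import itertools

    def site_likelihood(site):
        total = 0.0
        root = tree.root.name
        for fixed in itertools.product(
            range(N_SENSE), repeat=len(internals) - 1
        ):
            states = dict(zip((n.name for n in internals[:-1]), fixed))
            vec = pi.copy()  # indexed by the root state
            for node in tree.postorder:
                if node.parent is None:
                    continue
                parent = node.parent.name
                p = p_mats[node.name]
                if node.is_leaf:
                    s = enc[row_of[node.name], site]
                    col = np.ones(N_SENSE) if s == GAP_STATE else p[:, s]
                else:
                    col = p[:, states[node.name]]
                if parent == root:
                    vec = vec * col
                else:
                    vec = vec * (
                        np.ones(N_SENSE)
                        if node.is_leaf and enc[row_of[node.name], site] == GAP_STATE
                        else col[states[parent]]
                    )
            total += float(vec.sum())
        return total

    return sum(np.log(site_likelihood(s)) for s in range(aln.n_codons))


def random_instance(rng):
    newick = rng.choice(
        [
            "(a:{:.3f},b:{:.3f},c:{:.3f});",
            "((a:{:.3f},b:{:.3f}):{:.3f},(c:{:.3f},d:{:.3f}):{:.3f});",
            "(a:{:.3f},(b:{:.3f},(c:{:.3f},d:{:.3f}):{:.3f}):{:.3f});",
        ]
    )
    n_lens = newick.count("{")
    tree = al.Phylogeny.from_newick(
        newick.format(*rng.uniform(0.02, 0.8, size=n_lens))
    )
    pi = rng.dirichlet(np.ones(N_SENSE) * 5)
    kappa = float(rng.uniform(0.5, 6.0))
    omega_map = {b: float(rng.uniform(0.05, 3.0)) for b in tree.branches}
    n_sites = int(rng.integers(1, 6))
    rows = []
    for _ in tree.taxa:
        codons = [
            "---" if rng.random() < 0.1 else random_codon_seq(rng, 1)
            for _ in range(n_sites)
        ]
        rows.append("".join(codons))
    aln = CodonAlignment(list(tree.taxa), rows)
    return aln, tree, pi, kappa, omega_map


class TestRateMatrix:
    def test_rows_sum_to_zero(self):
        q = build_rate_matrix(np.full(N_SENSE, 1 / N_SENSE), 0.5, kappa=2.0)
        np.testing.assert_allclose(q.sum(axis=1), 0.0, atol=1e-12)

    def test_omega_zero_kills_nonsynonymous_rates(self):
        q = build_rate_matrix(np.full(N_SENSE, 1 / N_SENSE), 0.0, kappa=2.0)
        nonsyn = ONE_DIFF & ~IS_SYNONYMOUS
        assert np.all(q[nonsyn] == 0.0)

    def test_detailed_balance(self):
        rng = np.random.default_rng(0)
        pi = rng.dirichlet(np.ones(N_SENSE))
        q = build_rate_matrix(pi, 0.7, kappa=3.1)
        flow = pi[:, None] * q
        np.testing.assert_allclose(flow, flow.T, atol=1e-14)

    def test_default_scaling_one_substitution_per_codon(self):
        rng = np.random.default_rng(1)
        pi = rng.dirichlet(np.ones(N_SENSE))
        q = build_rate_matrix(pi, 0.3, kappa=2.0)
        assert -np.dot(pi, np.diag(q)) == pytest.approx(1.0)

    def test_zero_frequency_pseudo_count_warning(self):
        pi = np.zeros(N_SENSE)
        pi[:10] = 0.1
        with pytest.warns(UserWarning, match="pseudo-frequency"):
            q = build_rate_matrix(pi, 0.5, kappa=2.0)
        assert np.isfinite(q).all()


class TestLogLikelihood:
    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(33)
        for _ in range(10):
            aln, tree, pi, kappa, omega_map = random_instance(rng)
            params = CodonModelParams(kappa, omega_map, pi)
            got = log_likelihood(aln, tree, params)
            want = enumeration_lnl(aln, tree, pi, kappa, omega_map)
            assert got == pytest.approx(want, abs=1e-8)

    def test_mixture_is_weighted_average_of_class_likelihoods(self):
        rng = np.random.default_rng(4)
        tree = al.Phylogeny.from_newick("(a:0.2,(b:0.1,c:0.3 #1):0.15);")
        aln = CodonAlignment(
            list(tree.taxa), [random_codon_seq(rng, 4) for _ in tree.taxa]
        )
        pi = rng.dirichlet(np.ones(N_SENSE) * 5)
        mix = SiteClassMix(0.5, 0.3, 0.2, 4.0)
        params = CodonModelParams(2.0, {}, pi)
        got = log_likelihood(aln, tree, params, mix=mix)
        # oracle: per-site weighted sum of four single-class likelihoods,
        # all classes on the shared neutral-rate scale
        from altisel.codon_ml import gy94_mean_rate

        scale = gy94_mean_rate(pi, 2.0)
        weights = mix.proportions()
        site_liks = np.zeros(aln.n_codons)
        for k in range(4):
            omega_map = {
                b: mix.class_omegas(b in tree.foreground)[k]
                for b in tree.branches
            }
            per_site = [
                np.exp(
                    enumeration_lnl(
                        aln.take_columns([s]), tree, pi, 2.0, omega_map, scale
                    )
                )
                for s in range(aln.n_codons)
            ]
            site_liks = site_liks + weights[k] * np.array(per_site)
        assert got == pytest.approx(float(np.log(site_liks).sum()), abs=1e-8)

    def test_zero_lengths_identical_rows_give_log_pi_sum(self):
        tree = al.Phylogeny.from_newick("(a:0,b:0,c:0);")
        seq = "ATGAAAGGG"
        aln = CodonAlignment(["a", "b", "c"], [seq] * 3)
        pi = np.random.default_rng(2).dirichlet(np.ones(N_SENSE))
        params = CodonModelParams(2.0, {b: 0.5 for b in tree.branches}, pi)
        got = log_likelihood(aln, tree, params)
        expected = sum(np.log(pi[al._codons.CODON_INDEX[c]]) for c in
                       ("ATG", "AAA", "GGG"))
        assert got == pytest.approx(expected, abs=1e-10)

    def test_duplicating_columns_doubles_lnl(self, small_tree):
        rng = np.random.default_rng(3)
        aln = CodonAlignment(
            list(small_tree.taxa),
            [random_codon_seq(rng, 5) for _ in small_tree.taxa],
        )
        doubled = CodonAlignment(
            list(small_tree.taxa), [s + s for s in aln.sequences]
        )
        pi = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, {b: 0.4 for b in small_tree.branches}, pi)
        l1 = log_likelihood(aln, small_tree, params)
        l2 = log_likelihood(doubled, small_tree, params)
        assert l2 == pytest.approx(2 * l1, abs=1e-9)

    def test_all_gap_column_leaves_lnl_unchanged(self, small_tree):
        rng = np.random.default_rng(6)
        aln = CodonAlignment(
            list(small_tree.taxa),
            [random_codon_seq(rng, 4) for _ in small_tree.taxa],
        )
        padded = CodonAlignment(
            list(small_tree.taxa), [s + "---" for s in aln.sequences]
        )
        pi = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, {b: 0.4 for b in small_tree.branches}, pi)
        assert log_likelihood(padded, small_tree, params) == pytest.approx(
            log_likelihood(aln, small_tree, params), abs=1e-9
        )

    def test_invariant_to_row_order(self, small_tree):
        rng = np.random.default_rng(7)
        rows = [random_codon_seq(rng, 5) for _ in small_tree.taxa]
        aln = CodonAlignment(list(small_tree.taxa), rows)
        shuffled = CodonAlignment(
            list(small_tree.taxa)[::-1], rows[::-1]
        )
        pi = f3x4_frequencies(aln)
        params = CodonModelParams(2.0, {b: 0.4 for b in small_tree.branches}, pi)
        assert log_likelihood(aln, small_tree, params) == pytest.approx(
            log_likelihood(shuffled, small_tree, params), abs=1e-10
        )

    def test_invariant_to_rerooting(self):
        # same unrooted tree, two rootings; reversible model => same lnL
        rng = np.random.default_rng(9)
        rows = [random_codon_seq(rng, 6) for _ in range(4)]
        aln = CodonAlignment(["a", "b", "c", "d"], rows)
        t1 = al.Phylogeny.from_newick(
            "((a:0.1,b:0.2):0.05,(c:0.15,d:0.25):0.07);"
        )
        t2 = al.Phylogeny.from_newick(
            "(a:0.1,b:0.2,(c:0.15,d:0.25):0.12);"
        )
        pi = f3x4_frequencies(aln)
        p1 = CodonModelParams(2.0, {b: 0.4 for b in t1.branches}, pi)
        p2 = CodonModelParams(2.0, {b: 0.4 for b in t2.branches}, pi)
        assert log_likelihood(aln, t1, p1) == pytest.approx(
            log_likelihood(aln, t2, p2), abs=1e-9
        )

    def test_taxon_mismatch_rejected(self, small_tree):
        aln = CodonAlignment(["a", "b", "z"], ["AAA", "AAA", "AAA"])
        pi = np.full(N_SENSE, 1 / N_SENSE)
        params = CodonModelParams(2.0, {b: 0.5 for b in small_tree.branches}, pi)
        with pytest.raises(ValueError, match="taxa"):
            log_likelihood(aln, small_tree, params)

    def test_missing_branch_omega_rejected(self, small_tree):
        aln = CodonAlignment(
            list(small_tree.taxa), ["AAA", "AAA", "AAA"]
        )
        pi = np.full(N_SENSE, 1 / N_SENSE)
        params = CodonModelParams(2.0, {"a": 0.5}, pi)
        with pytest.raises(ValueError, match="omega_map missing"):
            log_likelihood(aln, small_tree, params)


class TestFits:
    def test_branch_model_single_class_equals_m0(self, m0_alignment):
        aln, tree = m0_alignment
        m0 = fit_m0(aln, tree)
        one_class = fit_branch(aln, tree, {b: "all" for b in tree.branches})
        assert abs(m0.lnl - one_class.lnl) < 1e-6

    def test_fitted_lnl_beats_generating_parameters(self, m0_alignment):
        aln, tree = m0_alignment
        fit = fit_m0(aln, tree)
        truth = CodonModelParams(
            2.0, {b: 0.2 for b in tree.branches}, fit.codon_freqs
        )
        assert fit.lnl >= log_likelihood(aln, tree, truth) - 1e-6

    def test_two_rate_partition_recovers_contrast(self):
        # one fast branch (omega 1.2) vs slow background (0.1)
        tree = al.Phylogeny.from_newick(
            "(o:0.3,(x:0.15,y:0.15):0.1);"
        )
        omega_truth = {b: 0.1 for b in tree.branches}
        omega_truth["x"] = 1.2
        params = al.SeqSimParams(
            tree=tree, kappa=2.0, omega_map=omega_truth, n_codons=600, seed=29
        )
        aln, _ = al.simulate_codon_alignment(params)
        partition = {b: ("fast" if b == "x" else "slow") for b in tree.branches}
        fit = fit_branch(aln, tree, partition)
        assert fit.omega_map["x"] > 2.5 * fit.omega_map["y"]


class TestLRT:
    def test_zero_statistic_gives_p_one(self):
        assert lrt(-100.0, -100.0, df=1) == 1.0

    def test_chi2_quantile_at_boundary(self):
        # 2*delta = 3.841 is the 5% point of chi-square(1)
        assert lrt(0.0, 3.841 / 2, df=1) == pytest.approx(0.05, abs=5e-4)

    def test_chi2_tail_value(self):
        assert lrt(0.0, 5.0, df=1) == pytest.approx(
            float(chi2.sf(10.0, 1)), rel=1e-12
        )
        assert lrt(0.0, 5.0, df=1) == pytest.approx(1.565e-3, rel=1e-3)

    def test_negative_delta_clipped(self):
        assert lrt(-50.0, -50.5, df=1) == 1.0

    def test_df_validated(self):
        with pytest.raises(ValueError, match="df"):
            lrt(0.0, 1.0, df=0)


class TestBranchSite:
    def test_low_information_flagged(self, study_tree):
        aln = CodonAlignment(
            list(study_tree.taxa), ["ATGAAAGGGTTT"] * 5
        )
        res = al.fit_branch_site(aln, study_tree)
        assert res.low_information
        assert res.lrt.statistic == pytest.approx(0.0, abs=1e-6)

    def test_requires_foreground(self, small_tree):
        aln = CodonAlignment(list(small_tree.taxa), ["ATGAAA"] * 3)
        with pytest.raises(ValueError, match="foreground"):
            al.fit_branch_site(aln, small_tree)

    def test_alt_never_below_null(self, study_tree):
        params = al.SeqSimParams(
            tree=study_tree,
            site_mix=SiteClassMix(0.7, 0.2, 0.2, 1.0),
            n_codons=120,
            seed=41,
        )
        aln, _ = al.simulate_codon_alignment(params)
        res = al.fit_branch_site(aln, study_tree)
        assert res.lrt.lnl_alt >= res.lrt.lnl_null - 1e-9
        assert res.lrt.statistic >= 0.0
        assert 0.0 <= res.lrt.p_value <= 1.0
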
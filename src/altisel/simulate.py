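"""Synthetic data generators mirroring the assumptions of the analyses.

Four generators cover the two halves of the selection scan:

* ``simulate_codon_alignment`` — GY94 evolution along a tree, optionally
  with branch-site model A site classes (i.i.d. across codons), so
  codon-model fits and LRT calibration can be studied with known truth;
* ``simulate_allele_counts`` — the island-model generative form of the
  F_ST outlier model: logit F_ST(i,j) = alpha_i + beta_j, ancestral
  frequencies Beta-distributed, population frequencies beta-binomial;
* ``simulate_genotypes`` — diploid genotypes from population frequencies
  with optional inbreeding;
* ``simulate_read_counts`` — Poisson sequencing depth with symmetric
  base-call errors, feeding the SNP caller.

All generators are deterministic in their seed; per-branch and
per-locus substreams are derived from it so results are stable under
any evaluation order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from ._codons import N_SENSE, SENSE_CODONS
from .alignment import CodonAlignment
from .codon_ml import (
    SiteClassMix,
    _eigen_gy94,
    gy94_mean_rate,
    transition_probabilities,
)
from .fst_outlier import AlleleCountTable, GenotypeMatrix
from .snp_tagging import ReadCountSite
from .trees import Phylogeny

__all__ = [
    "SeqSimParams",
    "IslandModelParams",
    "ReadSimParams",
    "uniform_codon_freqs",
    "simulate_codon_alignment",
    "simulate_allele_counts",
    "simulate_genotypes",
    "simulate_read_counts",
]


def uniform_codon_freqs() -> np.ndarray:
    """Equal frequency for each of the 61 sense codons."""
    return np.full(N_SENSE, 1.0 / N_SENSE)


# ---------------------------------------------------------------------------
# codon alignments
# ---------------------------------------------------------------------------


@dataclass
class SeqSimParams:
    """Settings for GY94 sequence simulation along a tree.

    Either ``omega_map`` assigns one omega per branch (M0 / branch
    models), or ``site_mix`` imposes branch-site model A classes using
    the tree's foreground flags.
    """

    tree: Phylogeny
    kappa: float = 2.0
    omega_map: dict[str, float] | None = None
    site_mix: SiteClassMix | None = None
    codon_freqs: np.ndarray = field(default_factory=uniform_codon_freqs)
    n_codons: int = 300
    seed: int = 0

    def __post_init__(self):
        self.codon_freqs = np.asarray(self.codon_freqs, dtype=float)
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.n_codons < 1:
            raise ValueError("n_codons must be >= 1")
        if self.codon_freqs.shape != (N_SENSE,):
            raise ValueError(f"codon_freqs must have length {N_SENSE}")
        if abs(self.codon_freqs.sum() - 1.0) > 1e-9:
            raise ValueError("codon_freqs must sum to 1 (within 1e-9)")
        if self.site_mix is None:
            if self.omega_map is None:
                raise ValueError("provide omega_map or site_mix")
            missing = [b for b in self.tree.branches if b not in self.omega_map]
            if missing:
                raise ValueError(f"omega_map missing branches: {missing}")
            if any(w < 0 for w in self.omega_map.values()):
                raise ValueError("omega values must be >= 0")
        elif self.site_mix is not None and not self.tree.foreground:
            raise ValueError("site_mix requires a foreground branch on the tree")


def simulate_codon_alignment(
    params: SeqSimParams,
) -> tuple[CodonAlignment, np.ndarray]:
    """Simulate an ungapped codon alignment under GY94.

    Returns the alignment (one row per leaf) and the per-site true class
    labels: all zeros for omega-map simulations, class indices 0-3 for
    branch-site simulations (2 and 3 are the positively selected
    classes on the foreground branch).
    """
    tree = params.tree
    if tree.n_leaves() < 2:
        raise ValueError("tree must have at least 2 leaves")
    n = params.n_codons
    pi = params.codon_freqs

    if params.site_mix is not None:
        mix = params.site_mix
        class_rng = np.random.default_rng([params.seed, 10_000])
        site_classes = class_rng.choice(4, size=n, p=mix.proportions())
        omega_sets = [
            {
                b: mix.class_omegas(b in tree.foreground)[k]
                for b in tree.branches
            }
            for k in range(4)
        ]
    else:
        site_classes = np.zeros(n, dtype=int)
        omega_sets = [dict(params.omega_map)]

    eig_cache: dict[float, tuple] = {}
    # site-class mixtures share the neutral-rate normalisation so that
    # relative substitution rates across classes follow omega (a class
    # with omega > 1 genuinely evolves faster); single-omega branches
    # use the standard per-matrix scaling, one substitution per codon
    # per unit branch length
    scale = (
        gy94_mean_rate(pi, params.kappa)
        if params.site_mix is not None
        else None
    )

    def eig_for(omega: float):
        if omega not in eig_cache:
            eig_cache[omega] = _eigen_gy94(
                pi, params.kappa, omega, scale_factor=scale
            )
        return eig_cache[omega]

    root_rng = np.random.default_rng([params.seed, 0])
    states = {tree.root.name: root_rng.choice(N_SENSE, size=n, p=pi)}
    # walk root->tips; each branch has its own deterministic substream
    for branch_no, node in enumerate(reversed(tree.postorder)):
        if node.parent is None:
            continue
        rng = np.random.default_rng([params.seed, 1 + branch_no])
        parent_states = states[node.parent.name]
        child = np.empty(n, dtype=np.int64)
        for k in range(len(omega_sets)):
            sel = site_classes == k if params.site_mix is not None else slice(None)
            sub_parent = parent_states[sel]
            if sub_parent.size == 0:
                continue
            p = transition_probabilities(
                eig_for(omega_sets[k][node.name]), node.length
            )
            p = p / p.sum(axis=1, keepdims=True)
            # inverse-CDF sampling per site, vectorised over states
            cdf = np.cumsum(p, axis=1)
            u = rng.random(sub_parent.size)
            drawn = np.array(
                [
                    np.searchsorted(cdf[s], x)
                    for s, x in zip(sub_parent, u)
                ]
            )
            child[sel] = np.minimum(drawn, N_SENSE - 1)
        states[node.name] = child

    taxa = list(tree.taxa)
    seqs = [
        "".join(SENSE_CODONS[s] for s in states[t]) for t in taxa
    ]
    aln = CodonAlignment(taxa, seqs, gene_id=f"sim_seed{params.seed}")
    return aln, site_classes


# ---------------------------------------------------------------------------
# island-model allele counts
# ---------------------------------------------------------------------------


@dataclass
class IslandModelParams:
    """Generative island model matching the outlier scan's likelihood."""

    n_pops: int = 5
    n_loci: int = 100
    beta: np.ndarray | float = -1.0
    alpha: np.ndarray | float = 0.0
    ancestral_freq_prior: tuple[float, float] = (1.0, 1.0)
    sample_sizes: np.ndarray | int = 40
    seed: int = 0

    def __post_init__(self):
        if self.n_pops < 2:
            raise ValueError("need n_pops >= 2: differentiation is undefined otherwise")
        if self.n_loci < 1:
            raise ValueError("need n_loci >= 1")
        self.beta = np.broadcast_to(
            np.asarray(self.beta, dtype=float), (self.n_pops,)
        ).copy()
        self.alpha = np.broadcast_to(
            np.asarray(self.alpha, dtype=float), (self.n_loci,)
        ).copy()
        self.sample_sizes = np.broadcast_to(
            np.asarray(self.sample_sizes, dtype=int), (self.n_pops,)
        ).copy()
        if (self.sample_sizes < 2).any():
            raise ValueError("sample sizes must be >= 2 alleles")
        if min(self.ancestral_freq_prior) <= 0:
            raise ValueError("Beta prior shapes must be positive")
        fst = expit(self.alpha[:, None] + self.beta[None, :])
        if ((fst <= 0) | (fst >= 1)).any():
            raise ValueError("implied F_ST values must lie strictly in (0, 1)")


def simulate_allele_counts(
    params: IslandModelParams,
) -> tuple[AlleleCountTable, dict]:
    """Draw allele counts under the island model with locus effects.

    Per locus i: ancestral frequency p_i ~ Beta(prior); population
    frequency q_ij ~ Beta(p_i * theta_ij, (1 - p_i) * theta_ij) with
    theta_ij = 1/F_ST(i,j) - 1 and logit F_ST(i,j) = alpha_i + beta_j;
    counts are binomial at the sample sizes. The truth record carries
    alpha, beta and the ancestral frequencies.
    """
    fst = expit(params.alpha[:, None] + params.beta[None, :])
    theta = 1.0 / fst - 1.0
    shape_a, shape_b = params.ancestral_freq_prior
    anc_rng = np.random.default_rng([params.seed, 0])
    p = anc_rng.beta(shape_a, shape_b, size=params.n_loci)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    a = np.empty((params.n_loci, params.n_pops), dtype=np.int64)
    freqs = np.empty((params.n_loci, params.n_pops))
    for i in range(params.n_loci):  # per-locus substreams
        rng = np.random.default_rng([params.seed, 1 + i])
        q = rng.beta(p[i] * theta[i], (1 - p[i]) * theta[i])
        q = np.clip(q, 0.0, 1.0)
        freqs[i] = q
        a[i] = rng.binomial(params.sample_sizes, q)
    totals = np.tile(params.sample_sizes, (params.n_loci, 1))
    locus_ids = [f"locus{i:04d}" for i in range(params.n_loci)]
    pops = [f"pop{j + 1}" for j in range(params.n_pops)]
    table = AlleleCountTable(locus_ids, pops, a, totals)
    truth = {
        "alpha": params.alpha.copy(),
        "beta": params.beta.copy(),
        "ancestral_freq": p,
        "pop_freqs": freqs,
        "fst": fst,
    }
    return table, truth


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------


def simulate_genotypes(
    pop_freqs,
    n_ind: int,
    inbreeding_f: float = 0.0,
    seed: int = 0,
) -> GenotypeMatrix:
    """Diploid genotypes per population with inbreeding coefficient F.

    `pop_freqs` is (n_loci, n_pops) alternate-allele frequencies; each
    population contributes `n_ind` individuals with genotype
    probabilities {(1-q)^2 + Fq(1-q), 2q(1-q)(1-F), q^2 + Fq(1-q)}.
    """
    freqs = np.atleast_2d(np.asarray(pop_freqs, dtype=float))
    if n_ind < 1:
        raise ValueError("n_ind must be >= 1")
    if not (0 <= inbreeding_f <= 1):
        raise ValueError("inbreeding coefficient must lie in [0, 1]")
    if ((freqs < 0) | (freqs > 1)).any():
        raise ValueError("allele frequencies must lie in [0, 1]")
    n_loci, n_pops = freqs.shape
    genotypes = np.empty((n_loci, n_pops * n_ind), dtype=np.int8)
    for j in range(n_pops):
        rng = np.random.default_rng([seed, j])
        q = freqs[:, j][:, None]
        het = 2 * q * (1 - q) * (1 - inbreeding_f)
        hom_alt = q**2 + inbreeding_f * q * (1 - q)
        u = rng.random((n_loci, n_ind))
        g = np.where(u < hom_alt, 2, np.where(u < hom_alt + het, 1, 0))
        genotypes[:, j * n_ind : (j + 1) * n_ind] = g
    individuals = [
        f"pop{j + 1}_ind{k + 1}" for j in range(n_pops) for k in range(n_ind)
    ]
    populations = [f"pop{j + 1}" for j in range(n_pops) for _ in range(n_ind)]
    return GenotypeMatrix(
        [f"locus{i:04d}" for i in range(n_loci)],
        individuals,
        populations,
        genotypes,
    )


# ---------------------------------------------------------------------------
# read counts
# ---------------------------------------------------------------------------


@dataclass
class ReadSimParams:
    mean_coverage: float = 250.0
    error_rate: float = 0.001
    seed: int = 0

    def __post_init__(self):
        if self.mean_coverage <= 0:
            raise ValueError("mean coverage must be positive")
        if not (0 <= self.error_rate < 0.5):
            raise ValueError("error rate must lie in [0, 0.5)")


def simulate_read_counts(
    site_freqs,
    params: ReadSimParams,
    gene_id: str = "gene",
    alleles: tuple[str, str] = ("A", "G"),
) -> list[ReadCountSite]:
    """Per-site read counts for a pooled sample of known allele frequencies.

    `site_freqs` gives the alternate-allele frequency at each site (the
    pooled frequency over sequenced individuals; a heterozygous single
    individual is frequency 0.5). Depth is Poisson(mean_coverage); each
    read reports the true allele with probability 1 - error_rate, else
    one of the three other bases uniformly.
    """
    freqs = np.asarray(site_freqs, dtype=float)
    ref, alt = alleles
    if ref == alt:
        raise ValueError("reference and alternate alleles must differ")
    bases = ("A", "C", "G", "T")
    others = {b: [x for x in bases if x != b] for b in bases}
    rng = np.random.default_rng([params.seed, 0])
    sites = []
    for pos, q in enumerate(freqs, start=1):
        depth = rng.poisson(params.mean_coverage)
        counts = dict.fromkeys(bases, 0)
        if depth > 0:
            n_alt_true = rng.binomial(depth, q)
            for base, n_true in ((alt, n_alt_true), (ref, depth - n_alt_true)):
                if n_true == 0:
                    continue
                n_err = rng.binomial(n_true, params.error_rate)
                counts[base] += n_true - n_err
                if n_err:
                    err_targets = rng.choice(3, size=n_err)
                    for t in err_targets:
                        counts[others[base][t]] += 1
        sites.append(
            ReadCountSite(
                gene_id=gene_id,
                position=pos,
                allele_counts={b: c for b, c in counts.items() if c > 0},
            )
        )
    return sites
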
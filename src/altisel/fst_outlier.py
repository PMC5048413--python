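"""Population-genetic selection scan on biallelic SNP data.

The centrepiece is a hierarchical Bayesian F_ST outlier model in the
style of BayeScan: for locus i and population j the logit of the
locus-population F_ST decomposes as alpha_i + beta_j, where beta_j is a
population (demographic) effect and alpha_i a locus-specific selection
effect. Allele counts follow a beta-binomial likelihood around an
ancestral frequency p_i with precision theta_ij = 1/F_ST(i,j) - 1.
A reversible-jump MCMC toggles each alpha_i in and out of the model;
the posterior inclusion probability yields a q-value, and the sign of
alpha classifies flagged loci: positive alpha = diversifying selection
(excess differentiation), negative = balancing selection (deficit).

Supporting per-locus QC: the Weir-Cockerham (1984) F_ST estimator,
the exact Hardy-Weinberg test, and a Markov-chain exact test of
linkage disequilibrium on two-locus genotype tables.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.special import betaln, expit, gammaln, logit

logger = logging.getLogger(__name__)

__all__ = [
    "GenotypeMatrix",
    "AlleleCountTable",
    "OutlierResult",
    "McmcSettings",
    "LdSettings",
    "BayescanResult",
    "allele_counts_from_genotypes",
    "wc_fst",
    "hwe_exact",
    "ld_test",
    "bayescan_scan",
    "qvalues_from_posterior",
    "classify_outliers",
    "transect_consistency",
]


# ---------------------------------------------------------------------------
# data containers
# ---------------------------------------------------------------------------


@dataclass
class GenotypeMatrix:
    """Diploid genotypes (alt-allele dosage 0/1/2, -1 = missing)."""

    locus_ids: list[str]
    individual_ids: list[str]
    populations: list[str]
    genotypes: np.ndarray  # (n_loci, n_individuals) int8
    gene_ids: list[str] | None = None

    def __post_init__(self):
        self.genotypes = np.asarray(self.genotypes, dtype=np.int8)
        if self.genotypes.shape != (len(self.locus_ids), len(self.individual_ids)):
            raise ValueError("genotype matrix shape mismatch")
        if len(self.populations) != len(self.individual_ids):
            raise ValueError("one population label per individual required")
        bad = ~np.isin(self.genotypes, [-1, 0, 1, 2])
        if bad.any():
            raise ValueError("genotypes must be in {-1, 0, 1, 2}")

    @property
    def population_names(self) -> list[str]:
        seen = []
        for p in self.populations:
            if p not in seen:
                seen.append(p)
        return seen

    def subset_populations(self, pops) -> "GenotypeMatrix":
        pops = set(pops)
        keep = [i for i, p in enumerate(self.populations) if p in pops]
        return GenotypeMatrix(
            list(self.locus_ids),
            [self.individual_ids[i] for i in keep],
            [self.populations[i] for i in keep],
            self.genotypes[:, keep],
            gene_ids=self.gene_ids,
        )

    def genotype_counts(self, locus_index: int, population: str):
        """(n_AA, n_Aa, n_aa) homozygote-ref / het / homozygote-alt counts."""
        mask = np.array([p == population for p in self.populations])
        g = self.genotypes[locus_index, mask]
        g = g[g >= 0]
        return int((g == 0).sum()), int((g == 1).sum()), int((g == 2).sum())

    # -- construction from standard formats ---------------------------

    @classmethod
    def from_vcf(cls, path, population_map: dict[str, str]) -> "GenotypeMatrix":
        """Read biallelic records from a VCF (GT field).

        `population_map` assigns each sample id to a population; samples
        missing from the map are dropped. Multi-allelic records are
        skipped with a log message. Genotypes become alt-allele dosage;
        any missing allele call marks the genotype missing.
        """
        from cyvcf2 import VCF

        reader = VCF(str(path))
        samples = [s for s in reader.samples if s in population_map]
        if not samples:
            raise ValueError("no VCF samples present in the population map")
        keep = [reader.samples.index(s) for s in samples]
        locus_ids, gene_ids, rows = [], [], []
        n_skipped = 0
        for variant in reader:
            if len(variant.ALT) != 1:
                n_skipped += 1
                continue
            row = []
            for idx in keep:
                alleles = variant.genotypes[idx][:2]
                if any(a < 0 for a in alleles):
                    row.append(-1)
                else:
                    row.append(int(alleles[0] > 0) + int(alleles[1] > 0))
            rows.append(row)
            locus_ids.append(variant.ID or f"{variant.CHROM}_{variant.POS}")
            gene_ids.append(variant.CHROM)
        if n_skipped:
            logger.info("skipped %d non-biallelic VCF records", n_skipped)
        return cls(
            locus_ids,
            samples,
            [population_map[s] for s in samples],
            np.array(rows, dtype=np.int8),
            gene_ids=gene_ids,
        )

    @classmethod
    def from_tsv(cls, path) -> "GenotypeMatrix":
        """Read a long-format table: locus_id, individual_id, population,
        genotype (0/1/2 alt-allele dosage, empty or -1 for missing)."""
        df = pd.read_csv(path, sep="\t", comment="#")
        required = {"locus_id", "individual_id", "population", "genotype"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"genotype table missing columns: {sorted(missing)}")
        loci = list(dict.fromkeys(df["locus_id"].astype(str)))
        inds = list(dict.fromkeys(df["individual_id"].astype(str)))
        pops = {}
        geno = np.full((len(loci), len(inds)), -1, dtype=np.int8)
        li = {x: i for i, x in enumerate(loci)}
        ij = {x: j for j, x in enumerate(inds)}
        for row in df.itertuples(index=False):
            ind = str(row.individual_id)
            pops[ind] = str(row.population)
            value = row.genotype
            geno[li[str(row.locus_id)], ij[ind]] = (
                -1 if pd.isna(value) else int(value)
            )
        return cls(loci, inds, [pops[i] for i in inds], geno)


@dataclass
class AlleleCountTable:
    """Alternate-allele counts a_ij and sampled-allele totals n_ij."""

    locus_ids: list[str]
    populations: list[str]
    alt_counts: np.ndarray  # (n_loci, n_pops)
    totals: np.ndarray  # (n_loci, n_pops)
    flagged_loci: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.alt_counts = np.asarray(self.alt_counts, dtype=np.int64)
        self.totals = np.asarray(self.totals, dtype=np.int64)
        shape = (len(self.locus_ids), len(self.populations))
        if self.alt_counts.shape != shape or self.totals.shape != shape:
            raise ValueError("allele count table shape mismatch")
        if (self.alt_counts < 0).any() or (self.alt_counts > self.totals).any():
            raise ValueError("need 0 <= alt count <= total")

    @property
    def n_loci(self) -> int:
        return len(self.locus_ids)

    @property
    def n_pops(self) -> int:
        return len(self.populations)

    def subset_populations(self, pops) -> "AlleleCountTable":
        idx = [self.populations.index(p) for p in pops]
        return AlleleCountTable(
            list(self.locus_ids), list(pops),
            self.alt_counts[:, idx], self.totals[:, idx],
        )

    def to_tsv(self, path, header_comment: str | None = None) -> None:
        rows = []
        for i, locus in enumerate(self.locus_ids):
            for j, pop in enumerate(self.populations):
                rows.append(
                    {
                        "locus_id": locus,
                        "pop": pop,
                        "allele1_count": int(self.alt_counts[i, j]),
                        "total": int(self.totals[i, j]),
                    }
                )
        df = pd.DataFrame(rows)
        with open(path, "w") as fh:
            if header_comment:
                for line in header_comment.splitlines():
                    fh.write(f"# {line}\n")
            df.to_csv(fh, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "AlleleCountTable":
        df = pd.read_csv(path, sep="\t", comment="#")
        loci = list(dict.fromkeys(df["locus_id"].astype(str)))
        pops = list(dict.fromkeys(df["pop"].astype(str)))
        a = np.zeros((len(loci), len(pops)), dtype=np.int64)
        n = np.zeros_like(a)
        li = {x: i for i, x in enumerate(loci)}
        pj = {x: j for j, x in enumerate(pops)}
        for row in df.itertuples(index=False):
            i, j = li[str(row.locus_id)], pj[str(row.pop)]
            a[i, j] = row.allele1_count
            n[i, j] = row.total
        return cls(loci, pops, a, n)


@dataclass
class OutlierResult:
    locus_id: str
    alpha_mean: float
    alpha_sd: float
    inclusion_prob: float
    q_value: float
    fst_locus: float
    selection_class: str = "neutral"  # diversifying | balancing | neutral


@dataclass
class McmcSettings:
    """Run control for the outlier scan (BayeScan-equivalent defaults)."""

    n_iter: int = 100_000
    burn_in: int = 50_000
    thinning: int = 10
    n_pilot: int = 20
    pilot_length: int = 2_000
    prior_odds_neutral: float = 10.0
    seed: int = 0

    def __post_init__(self):
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thinning < 1:
            raise ValueError("thinning must be >= 1")
        if self.prior_odds_neutral <= 0:
            raise ValueError("prior odds must be positive")


@dataclass
class LdSettings:
    """Markov-chain run control for the exact LD test."""

    dememorization: int = 10_000
    n_batches: int = 100
    batch_length: int = 5_000
    seed: int = 0


@dataclass
class BayescanResult:
    results: list[OutlierResult]
    beta_mean: np.ndarray
    beta_sd: np.ndarray
    populations: list[str]
    excluded_monomorphic: list[str]
    acceptance: dict[str, float]
    flagged_run: bool = False

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "locus_id": r.locus_id,
                    "fst": r.fst_locus,
                    "alpha_mean": r.alpha_mean,
                    "alpha_sd": r.alpha_sd,
                    "inclusion_prob": r.inclusion_prob,
                    "q_value": r.q_value,
                    "class": r.selection_class,
                }
                for r in self.results
            ]
        )


# ---------------------------------------------------------------------------
# counts and F_ST
# ---------------------------------------------------------------------------


def allele_counts_from_genotypes(g: GenotypeMatrix) -> AlleleCountTable:
    """Tally alternate alleles per population; missing genotypes drop out."""
    pops = g.population_names
    masks = [np.array([p == pop for p in g.populations]) for pop in pops]
    a = np.zeros((len(g.locus_ids), len(pops)), dtype=np.int64)
    n = np.zeros_like(a)
    for j, mask in enumerate(masks):
        sub = g.genotypes[:, mask]
        observed = sub >= 0
        a[:, j] = np.where(observed, sub, 0).sum(axis=1)
        n[:, j] = 2 * observed.sum(axis=1)
    flagged = [
        g.locus_ids[i]
        for i in range(len(g.locus_ids))
        if (n[i] == 0).any()
    ]
    if flagged:
        logger.warning(
            "%d loci have a population with no genotyped individuals", len(flagged)
        )
    return AlleleCountTable(list(g.locus_ids), pops, a, n, flagged_loci=flagged)


def wc_fst(counts: AlleleCountTable):
    """Weir-Cockerham (1984) F_ST from allele counts.

    Uses the allele-level (haploid-sample) analysis of variance: with
    per-population allele frequencies p_j and sample sizes n_j,
    theta = (MSP - MSG) / (MSP + (n_c - 1) MSG). Loci monomorphic
    across all populations are undefined (NaN); the global estimate is
    the ratio of summed variance components across informative loci.
    """
    a = counts.alt_counts.astype(float)
    n = counts.totals.astype(float)
    per_locus = np.full(counts.n_loci, np.nan)
    num_sum = 0.0
    den_sum = 0.0
    for i in range(counts.n_loci):
        use = n[i] > 0
        if use.sum() < 2:
            continue
        nj = n[i, use]
        pj = a[i, use] / nj
        r = len(nj)
        n_tot = nj.sum()
        p_bar = (nj * pj).sum() / n_tot
        if p_bar <= 0 or p_bar >= 1:
            continue  # monomorphic across populations
        nc = (n_tot - (nj**2).sum() / n_tot) / (r - 1)
        msp = (nj * (pj - p_bar) ** 2).sum() / (r - 1)
        msg = (nj * pj * (1 - pj)).sum() / (n_tot - r)
        num = msp - msg
        den = msp + (nc - 1) * msg
        if den > 0:
            per_locus[i] = num / den
        num_sum += num
        den_sum += den
    global_fst = num_sum / den_sum if den_sum > 0 else float("nan")
    return {"per_locus_fst": per_locus, "global_fst": float(global_fst)}


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------


def _hwe_log_probs(n_a: int, n_total: int) -> tuple[np.ndarray, np.ndarray]:
    """Conditional distribution of the heterozygote count.

    Given n diploids and n_a copies of the minor-or-major allele A, the
    probability of h heterozygotes under random union of gametes is
    P(h) = n! 2^h n_A! n_a! / (n_AA! h! n_aa! (2n)!), h stepping by 2.
    Returns (h values, log probabilities).
    """
    n_b = 2 * n_total - n_a
    h_min = n_a % 2
    h_max = min(n_a, n_b)
    hs = np.arange(h_min, h_max + 1, 2)
    n_aa = (n_a - hs) // 2
    n_bb = (n_b - hs) // 2
    logp = (
        gammaln(n_total + 1)
        - gammaln(n_aa + 1)
        - gammaln(hs + 1)
        - gammaln(n_bb + 1)
        + hs * math.log(2)
        + gammaln(n_a + 1)
        + gammaln(n_b + 1)
        - gammaln(2 * n_total + 1)
    )
    return hs, logp - _logsumexp(logp)


def _logsumexp(x: np.ndarray) -> float:
    m = np.max(x)
    return float(m + np.log(np.exp(x - m).sum()))


def hwe_exact(
    n_aa_hom: int, n_het: int, n_bb_hom: int,
    method: str = "exact",
    mc_steps: int = 1_000_000,
    dememorization: int = 100_000,
    seed: int = 0,
) -> float:
    """Exact test of Hardy-Weinberg proportions for a biallelic locus.

    Conditions on the observed allele counts and sums the probabilities
    of all heterozygote counts no more probable than the observed one.
    `method="mc"` estimates the same p-value with a Markov chain over
    heterozygote counts (useful only as a cross-check; the closed form
    is exact and fast for any sample size).
    """
    if min(n_aa_hom, n_het, n_bb_hom) < 0 or n_aa_hom + n_het + n_bb_hom < 1:
        raise ValueError("genotype counts must be >= 0 and sum to >= 1")
    n = n_aa_hom + n_het + n_bb_hom
    n_a = 2 * n_aa_hom + n_het
    if n_a == 0 or n_a == 2 * n:
        return 1.0
    hs, logp = _hwe_log_probs(n_a, n)
    obs = np.where(hs == n_het)[0][0]
    tol = 1e-12
    if method == "exact":
        keep = logp <= logp[obs] + tol
        return float(min(1.0, np.exp(_logsumexp(logp[keep]))))
    if method != "mc":
        raise ValueError(f"unknown method {method!r}")
    rng = np.random.default_rng(seed)
    idx = int(obs)
    hits = 0
    for step in range(-dememorization, mc_steps):
        prop = idx + rng.choice((-1, 1))
        if 0 <= prop < len(hs) and math.log(rng.random()) < logp[prop] - logp[idx]:
            idx = prop
        if step >= 0 and logp[idx] <= logp[obs] + tol:
            hits += 1
    return hits / mc_steps


# ---------------------------------------------------------------------------
# linkage disequilibrium: Markov-chain exact test on genotype tables
# ---------------------------------------------------------------------------


def ld_test(
    genotypes_a: np.ndarray,
    genotypes_b: np.ndarray,
    settings: LdSettings | None = None,
) -> tuple[float, float]:
    """Probability test of genotypic linkage disequilibrium.

    Builds the two-locus genotype contingency table over individuals
    typed at both loci and runs a Metropolis chain over tables with the
    observed margins; the p-value is the equilibrium probability of
    tables no more probable than the observed one, estimated in batches
    (mean over batches, with its standard error returned alongside).
    Either locus monomorphic gives p = 1 by convention.
    """
    settings = settings or LdSettings()
    ga = np.asarray(genotypes_a)
    gb = np.asarray(genotypes_b)
    if ga.shape != gb.shape:
        raise ValueError("the two loci must cover the same individuals")
    keep = (ga >= 0) & (gb >= 0)
    ga, gb = ga[keep], gb[keep]
    cats_a = np.unique(ga)
    cats_b = np.unique(gb)
    if len(cats_a) < 2 or len(cats_b) < 2:
        logger.warning("monomorphic locus in LD test; p = 1 by convention")
        return 1.0, 0.0
    table = np.zeros((len(cats_a), len(cats_b)), dtype=np.int64)
    for x, y in zip(ga, gb):
        table[np.searchsorted(cats_a, x), np.searchsorted(cats_b, y)] += 1

    def log_prob(t):
        return -gammaln(t + 1).sum()

    rng = np.random.default_rng(settings.seed)
    obs_lp = log_prob(table)
    current = table.copy()
    current_lp = obs_lp
    nr, nc = current.shape
    tol = 1e-9

    def step():
        nonlocal current_lp
        i1, i2 = rng.choice(nr, 2, replace=False)
        j1, j2 = rng.choice(nc, 2, replace=False)
        if current[i1, j2] == 0 or current[i2, j1] == 0:
            return
        # diagonal +/- move preserving both margins; MH ratio in counts
        ratio = (current[i1, j2] * current[i2, j1]) / (
            (current[i1, j1] + 1) * (current[i2, j2] + 1)
        )
        if rng.random() < ratio:
            current[i1, j1] += 1
            current[i2, j2] += 1
            current[i1, j2] -= 1
            current[i2, j1] -= 1
            current_lp = log_prob(current)

    for _ in range(settings.dememorization):
        step()
    batch_means = np.empty(settings.n_batches)
    for b in range(settings.n_batches):
        hits = 0
        for _ in range(settings.batch_length):
            step()
            if current_lp <= obs_lp + tol:
                hits += 1
        batch_means[b] = hits / settings.batch_length
    p = float(batch_means.mean())
    se = float(batch_means.std(ddof=1) / math.sqrt(settings.n_batches))
    return p, se


# ---------------------------------------------------------------------------
# BayeScan-style outlier scan
# ---------------------------------------------------------------------------

_ALPHA_PRIOR_SD = 1.0
_BETA_PRIOR_MEAN = -1.0
_BETA_PRIOR_SD = 1.8


def _loglik_matrix(a, n, alpha_inc, beta, p):
    """Beta-binomial log-likelihood per (locus, population) cell."""
    fst = expit(alpha_inc[:, None] + beta[None, :])
    theta = 1.0 / fst - 1.0
    shape1 = p[:, None] * theta
    shape2 = (1.0 - p[:, None]) * theta
    return betaln(a + shape1, n - a + shape2) - betaln(shape1, shape2)


class _ScanChain:
    """Vectorised MCMC state for the outlier model."""

    def __init__(self, a, n, settings: McmcSettings, rng):
        self.a = a.astype(float)
        self.n = n.astype(float)
        self.L, self.J = a.shape
        self.settings = settings
        self.rng = rng
        pooled = (a.sum(axis=1) + 1.0) / (n.sum(axis=1) + 2.0)
        self.p = np.clip(pooled, 0.01, 0.99)
        self.alpha = np.zeros(self.L)
        self.include = np.zeros(self.L, dtype=bool)
        self.beta = np.full(self.J, _BETA_PRIOR_MEAN)
        self.sd_alpha = 0.5
        self.sd_p = 0.4  # on the logit scale
        self.sd_beta = np.full(self.J, 0.3)
        self.ll = self._full_ll()
        self.accept = {"alpha": [], "p": [], "beta": [], "jump": []}

    def _full_ll(self):
        return _loglik_matrix(
            self.a, self.n, self.alpha * self.include, self.beta, self.p
        )

    def update_p(self):
        z = logit(self.p)
        prop = z + self.rng.normal(0.0, self.sd_p, self.L)
        p_new = expit(prop)
        ll_new = _loglik_matrix(
            self.a, self.n, self.alpha * self.include, self.beta, p_new
        )
        # uniform prior on p => log-Jacobian log(p(1-p)) for the logit walk
        log_ratio = (
            ll_new.sum(axis=1) - self.ll.sum(axis=1)
            + np.log(p_new * (1 - p_new)) - np.log(self.p * (1 - self.p))
        )
        acc = np.log(self.rng.random(self.L)) < log_ratio
        self.p[acc] = p_new[acc]
        self.ll[acc] = ll_new[acc]
        self.accept["p"].append(acc.mean())

    def update_alpha(self):
        inc = self.include
        if not inc.any():
            return
        prop = self.alpha.copy()
        prop[inc] += self.rng.normal(0.0, self.sd_alpha, inc.sum())
        ll_new = _loglik_matrix(self.a, self.n, prop * inc, self.beta, self.p)
        log_ratio = (
            ll_new.sum(axis=1) - self.ll.sum(axis=1)
            + (self.alpha**2 - prop**2) / (2 * _ALPHA_PRIOR_SD**2)
        )
        acc = inc & (np.log(self.rng.random(self.L)) < log_ratio)
        self.alpha[acc] = prop[acc]
        self.ll[acc] = ll_new[acc]
        if inc.sum():
            self.accept["alpha"].append(acc.sum() / inc.sum())

    def update_beta(self):
        acc_count = 0
        for j in range(self.J):
            prop_beta = self.beta.copy()
            prop_beta[j] += self.rng.normal(0.0, self.sd_beta[j])
            beta_col = np.full(self.L, prop_beta[j])
            fst = expit(self.alpha * self.include + beta_col)
            theta = 1.0 / fst - 1.0
            s1 = self.p * theta
            s2 = (1.0 - self.p) * theta
            ll_col = betaln(self.a[:, j] + s1, self.n[:, j] - self.a[:, j] + s2) - betaln(s1, s2)
            log_ratio = (
                ll_col.sum() - self.ll[:, j].sum()
                + ((self.beta[j] - _BETA_PRIOR_MEAN) ** 2
                   - (prop_beta[j] - _BETA_PRIOR_MEAN) ** 2)
                / (2 * _BETA_PRIOR_SD**2)
            )
            if math.log(self.rng.random()) < log_ratio:
                self.beta[j] = prop_beta[j]
                self.ll[:, j] = ll_col
                acc_count += 1
        self.accept["beta"].append(acc_count / self.J)

    def update_inclusion(self):
        """Reversible-jump toggle of alpha_i, proposing alpha* from its prior.

        With the prior as proposal, the Jacobian/proposal terms cancel
        and the acceptance ratio reduces to the likelihood ratio times
        the prior model odds.
        """
        prop_include = ~self.include
        prop_alpha = np.where(
            self.include, self.alpha,
            self.rng.normal(0.0, _ALPHA_PRIOR_SD, self.L),
        )
        ll_new = _loglik_matrix(
            self.a, self.n, prop_alpha * prop_include, self.beta, self.p
        )
        log_odds = math.log(self.settings.prior_odds_neutral)
        # birth (neutral -> selected) pays the prior odds; death earns it
        log_ratio = (
            ll_new.sum(axis=1) - self.ll.sum(axis=1)
            + np.where(self.include, log_odds, -log_odds)
        )
        acc = np.log(self.rng.random(self.L)) < log_ratio
        self.include[acc] = prop_include[acc]
        self.alpha[acc] = prop_alpha[acc]
        self.ll[acc] = ll_new[acc]
        self.accept["jump"].append(acc.mean())

    def iterate(self):
        self.update_p()
        self.update_beta()
        self.update_alpha()
        self.update_inclusion()

    def tune(self):
        """Pilot-run proposal adaptation toward ~30% acceptance."""
        for key, attr in (("p", "sd_p"), ("alpha", "sd_alpha")):
            rates = self.accept[key]
            if rates:
                rate = float(np.mean(rates))
                factor = 1.5 if rate > 0.45 else (1 / 1.5 if rate < 0.15 else 1.0)
                setattr(self, attr, getattr(self, attr) * factor)
        rates = self.accept["beta"]
        if rates:
            rate = float(np.mean(rates))
            factor = 1.5 if rate > 0.45 else (1 / 1.5 if rate < 0.15 else 1.0)
            self.sd_beta *= factor
        self.accept = {k: [] for k in self.accept}


def bayescan_scan(
    counts: AlleleCountTable, settings: McmcSettings | None = None
) -> BayescanResult:
    """Run the hierarchical Bayesian F_ST outlier scan.

    Loci monomorphic across all populations carry no information about
    differentiation and are excluded up front (logged and reported).
    Reproducible for a fixed `settings.seed`.
    """
    settings = settings or McmcSettings()
    if counts.n_pops < 2:
        raise ValueError("need at least 2 populations")
    if counts.n_loci < 2:
        raise ValueError("need at least 2 loci")
    mono = (counts.alt_counts.sum(axis=1) == 0) | (
        counts.alt_counts.sum(axis=1) == counts.totals.sum(axis=1)
    )
    excluded = [counts.locus_ids[i] for i in np.where(mono)[0]]
    if excluded:
        logger.info("excluding %d monomorphic loci from the scan", len(excluded))
    keep = ~mono
    a = counts.alt_counts[keep]
    n = counts.totals[keep]
    locus_ids = [x for x, k in zip(counts.locus_ids, keep) if k]
    if len(locus_ids) < 2:
        raise ValueError("fewer than 2 polymorphic loci")

    rng = np.random.default_rng(settings.seed)
    chain = _ScanChain(a, n, settings, rng)
    for _ in range(settings.n_pilot):
        for _ in range(settings.pilot_length):
            chain.iterate()
        chain.tune()

    n_kept = 0
    L = len(locus_ids)
    sum_inc = np.zeros(L)
    sum_alpha = np.zeros(L)
    sum_alpha2 = np.zeros(L)
    n_alpha = np.zeros(L)
    sum_fst = np.zeros(L)
    sum_beta = np.zeros(chain.J)
    sum_beta2 = np.zeros(chain.J)
    for it in range(settings.n_iter):
        chain.iterate()
        if it < settings.burn_in or (it - settings.burn_in) % settings.thinning:
            continue
        n_kept += 1
        sum_inc += chain.include
        sum_alpha += np.where(chain.include, chain.alpha, 0.0)
        sum_alpha2 += np.where(chain.include, chain.alpha**2, 0.0)
        n_alpha += chain.include
        fst_mat = expit(
            chain.alpha[:, None] * chain.include[:, None] + chain.beta[None, :]
        )
        sum_fst += fst_mat.mean(axis=1)
        sum_beta += chain.beta
        sum_beta2 += chain.beta**2

    inclusion = sum_inc / n_kept
    with np.errstate(invalid="ignore"):
        alpha_mean = np.where(n_alpha > 0, sum_alpha / np.maximum(n_alpha, 1), 0.0)
        alpha_var = np.where(
            n_alpha > 1,
            sum_alpha2 / np.maximum(n_alpha, 1) - alpha_mean**2,
            0.0,
        )
    alpha_sd = np.sqrt(np.maximum(alpha_var, 0.0))
    fst_mean = sum_fst / n_kept
    beta_mean = sum_beta / n_kept
    beta_sd = np.sqrt(np.maximum(sum_beta2 / n_kept - beta_mean**2, 0.0))
    q = qvalues_from_posterior(inclusion)

    acceptance = {
        k: float(np.mean(v)) if v else float("nan")
        for k, v in chain.accept.items()
    }
    flagged = any(
        not math.isnan(r) and r < 0.05
        for key, r in acceptance.items()
        if key in ("alpha", "p")
    )
    if flagged:
        logger.warning("low MCMC acceptance after pilots: %s", acceptance)

    results = [
        OutlierResult(
            locus_id=locus_ids[i],
            alpha_mean=float(alpha_mean[i]),
            alpha_sd=float(alpha_sd[i]),
            inclusion_prob=float(inclusion[i]),
            q_value=float(q[i]),
            fst_locus=float(fst_mean[i]),
        )
        for i in range(L)
    ]
    results = classify_outliers(results)
    return BayescanResult(
        results=results,
        beta_mean=beta_mean,
        beta_sd=beta_sd,
        populations=list(counts.populations),
        excluded_monomorphic=excluded,
        acceptance=acceptance,
        flagged_run=flagged,
    )


def qvalues_from_posterior(inclusion_probs) -> np.ndarray:
    """FDR-style q-values from posterior inclusion probabilities.

    q_i is the mean posterior probability of neutrality (1 - P) among
    all loci at least as strongly supported as locus i.
    """
    p = np.asarray(inclusion_probs, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("inclusion probabilities must lie in [0, 1]")
    order = np.argsort(-p, kind="stable")
    one_minus = 1.0 - p[order]
    cummean = np.cumsum(one_minus) / np.arange(1, len(p) + 1)
    # equal posterior probabilities share the same (final) q-value
    q_sorted = cummean.copy()
    for i in range(len(p) - 2, -1, -1):
        if p[order[i]] == p[order[i + 1]]:
            q_sorted[i] = q_sorted[i + 1]
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def classify_outliers(
    results: list[OutlierResult], q_threshold: float = 0.05
) -> list[OutlierResult]:
    """Assign the selection class from q-value and the sign of alpha."""
    out = []
    for r in results:
        if r.q_value < q_threshold:
            if r.alpha_mean > 0:
                cls = "diversifying"
            elif r.alpha_mean < 0:
                cls = "balancing"
            else:
                logger.warning(
                    "locus %s significant with alpha exactly 0", r.locus_id
                )
                cls = "neutral"
        else:
            cls = "neutral"
        out.append(replace(r, selection_class=cls))
    return out


def transect_consistency(
    global_results: list[OutlierResult],
    local_results: list[list[OutlierResult]],
) -> pd.DataFrame:
    """Loci flagged as outliers in the global scan and in every local scan.

    Independent inter-altitude comparisons (transects) guard against
    false positives: only loci non-neutral in all analyses survive.
    Returns one row per consistent locus with the per-analysis class
    and whether the classes agree.
    """
    analyses = [global_results, *local_results]
    maps = [{r.locus_id: r for r in res} for res in analyses]
    common = set(maps[0])
    for m in maps[1:]:
        common &= set(m)
    skipped = set().union(*maps) - common
    if skipped:
        # e.g. loci monomorphic within one transect: no evidence there,
        # so they cannot be consistent outliers
        logger.info(
            "%d loci absent from at least one analysis are skipped", len(skipped)
        )
    names = ["global"] + [f"local{i + 1}" for i in range(len(local_results))]
    rows = []
    for locus in sorted(common):
        classes = [m[locus].selection_class for m in maps]
        if all(c != "neutral" for c in classes):
            rows.append(
                {
                    "locus_id": locus,
                    **dict(zip(names, classes)),
                    "class_agreement": len(set(classes)) == 1,
                }
            )
    return pd.DataFrame(
        rows, columns=["locus_id", *names, "class_agreement"]
    )
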
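# Methods

`altisel` implements a comparative selection scan of the kind used to
look for the genetic basis of altitudinal adaptation in non-model
amphibians: protein-coding orthologs from two species pairs (a
high-altitude lineage and its low-altitude relative in each pair, plus
an outgroup) are tested for accelerated evolution and episodic positive
selection with codon models, and a panel of tag SNPs genotyped in
populations along altitudinal transects is scanned for F_ST outliers
with a hierarchical Bayesian model. Every stage can run on synthetic
data with known truth, which is how the package validates itself.

## Codon models

### Substitution model

All sequence-level tests use the Goldman–Yang (1994) codon model over
the 61 sense codons of the universal code. The instantaneous rate from
codon x to codon y is zero if they differ at more than one position and
otherwise proportional to pi_y, multiplied by kappa for transitions and
by omega (dN/dS) for nonsynonymous changes. Equilibrium frequencies pi
come from F3x4 — empirical nucleotide frequencies at each codon
position, renormalised over sense codons — with a pseudocount of 0.1
per nucleotide so sparse alignments never produce zero frequencies.
Stop codons are not states; codons containing gaps or ambiguity codes
are treated as missing data at their tips.

Rate-matrix scaling follows two conventions, deliberately:

* single-omega models (M0 and the branch model) normalise each matrix
  to one expected substitution per codon, the standard unit in which
  branch lengths are reported;
* site-class mixtures (branch-site model A) normalise **all** class
  matrices by the neutral-class (omega = 1) rate. Within a mixture the
  classes must share one clock: self-normalising each class would force
  a site under omega = 5 to accumulate substitutions at the same total
  rate as a conserved site, erasing precisely the rate elevation the
  branch-site test looks for. Under the shared scale a branch length is
  the expected number of substitutions per codon at a neutrally
  evolving site. For single-class models the two conventions differ
  only by a relabelling of branch lengths; estimates of kappa and omega
  are unaffected.

The simulator (`simulate.simulate_codon_alignment`) is the exact
generative counterpart of the likelihood: same matrices, same scaling,
site classes i.i.d. across codons, with true class labels returned for
power and error bookkeeping.

### Likelihood and optimisation

Likelihoods are computed by Felsenstein pruning over compressed site
patterns, with per-node rescaling to avoid underflow. Transition
matrices come from the symmetric eigendecomposition available for
reversible models; decompositions and whole per-class site-likelihood
vectors are cached, so coordinate-wise optimisation (which re-evaluates
the same points often) costs far less than its raw evaluation count.

Fitting maximises lnL by coordinate sweeps: each branch length is
optimised by bounded Brent on a one-dimensional profile built from
inside/outside partial vectors (one propagation per candidate length
instead of a full pruning pass), then kappa, the omega parameters, and
— for model A — the class proportions, whose subproblem is cheap
because class likelihoods do not depend on the proportions. Bounds are
omega in [1e-4, 999], kappa in [0.1, 99], branch lengths in [0, 50];
omega-like parameters are searched in log space. Because coordinate
descent converges geometrically along a nearly fixed direction, every
sweep after the second attempts an extrapolated jump along the last
parameter step (factors 2 and 6), accepted only if it improves lnL;
this cuts typical fits from ~30 sweeps to under 10. A sweep that
improves lnL by less than 1e-4 ends the fit; fits that exhaust the
sweep budget are flagged `converged=False` rather than raised, and the
bootstrap counts them as missing replicates.

Two caveats worth knowing. First, with a time-reversible model a
rooted binary root makes only the *sum* of the two root-adjacent branch
lengths identifiable; per-branch-omega fits on such trees can wander on
a ridge. Use a trifurcating root (the natural unrooted representation),
as the bundled study tree does. Second, branch-site model A under the
null makes the selected-class weight unidentifiable, so the alternative
fit restarts the class proportions at an interior point before freeing
omega2 — otherwise omega2 has no gradient and the fit cannot leave the
null.

### The positive-selection test

`fit_branch_site` fits model A twice: the null with omega2 fixed at 1
and the alternative with omega2 free in [1, 999], warm-started from the
null so lnL_alt >= lnL_null by construction. The test statistic
2(lnL_alt - lnL_null) is clipped at zero and referred to chi-square
with one degree of freedom. The chi-square(1) reference (rather than
the 50:50 mixture of point mass and chi-square) is conservative because
the null pins omega2 at its boundary; simulation under the null shows
rejection rates well below the nominal 0.05. Genes with p below the
threshold (0.05, following common practice for transcriptome scans)
are putative positively selected genes (PSGs); BH q-values are also
reported downstream since scans of thousands of genes rarely survive
FDR control at these effect sizes.

Power at realistic settings is modest by nature: a terminal foreground
branch of ~0.1 substitutions/codon with omega2 = 5 on ~10% of sites
yields single-digit expected informative substitutions per 300-codon
gene. The calibration experiments in the test suite measure exactly
this: type-I error under the null and a strictly higher rejection rate
under planted selection, not high absolute power.

## Orthology and alignment QC

One-to-one orthologs are best reciprocal hits (BRH): a pair (a, b) is
kept iff b is a's highest-bit-score subject, a is b's, and both
supporting e-values pass 1e-10. Ties on bit score break by lower
e-value, then lexicographic subject id, and tie-broken pairs are
flagged in the output because tie resolution is a convention, not
biology. Hit tables are BLAST outfmt-6; for fixture-scale work a
built-in translated search (six-frame translation + Smith–Waterman via
Biopython's PairwiseAligner, BLOSUM62, gaps -11/-1) produces ranked
hits with a crude ungapped Karlin–Altschul e-value. That e-value is a
stand-in adequate for ranking tiny fixtures; production inputs should
come from a real search engine.

Alignment QC applies, in order: validation (internal stop codons
anywhere but the final column; length below 200 nt), column trimming
(drop any codon column whose gap-or-ambiguity fraction exceeds a
threshold, default 0 — a transparent stand-in for block-based trimmers,
chosen because it is exactly testable), and a synonymous-saturation
filter. Saturation is operationalised as any pairwise Nei–Gojobori
(1986) dS exceeding a cap (default 3.0) or being undefined (Jukes–
Cantor correction impossible, synonymous proportion >= 3/4). The NG86
implementation counts mutations to stop codons as nonsynonymous and
averages equally over substitution pathways, matching the widely used
convention (and Biopython's, against which it is cross-checked in the
tests). One honest limitation: for truly saturated pairs the
JC-corrected dS *estimate* concentrates just below 3 (its asymptotic
mean is ~2.9 when the true distance diverges), so the dS-cap filter
catches most, not all, saturated genes; the undefined-dS rule catches
the rest about half the time. The filter is a guard rail, not a sharp
classifier.

## Rate comparisons and category statistics

Per-branch evolutionary rates come from the branch model on the
concatenation of all retained orthologs. Uncertainty comes from
bootstrapping codon columns (the resampling unit that preserves the
codon model), refitting each replicate warm-started from the point
estimate. The high-vs-low comparison counts replicates in which the
high-altitude branch has the larger omega (paired within a replicate;
ties count half) and refers the count to an exact two-sided
Binomial(n, 1/2) test. Two statistical facts are documented rather
than hidden: the exact p-value is discrete (hence only approximately
uniform under an exchangeable null), and because bootstrap replicates
centre on the *observed* difference, the paired sign test is a
descriptive overlap measure, not a calibrated test of the null of equal
rates — which is also how the original transcriptome-scan usage should
be read.

Category-level rates average per-gene omega (branch-model estimate on
the designated high-altitude branch) within each functional category of
at least 5 genes; significance of "higher than the transcriptome
average" comes from resampling same-size gene sets without replacement
(add-one upper-tail p), with BH FDR across categories.
Over-representation of PSGs in a category uses the hypergeometric
upper tail with BH q-values. GO structure is taken as given — no
ancestor propagation.

## F_ST outlier scan

The outlier model decomposes differentiation locus by locus:
logit F_ST(i, j) = alpha_i + beta_j, with population effect beta_j ~
N(-1, 1.8), locus selection effect alpha_i ~ N(0, 1), and ancestral
frequencies p_i uniform. Counts a_ij are beta-binomial with shapes
p_i * theta_ij and (1 - p_i) * theta_ij, theta_ij = 1/F_ST - 1. A
reversible-jump step toggles each alpha_i, proposing from its prior (so
the acceptance ratio is the likelihood ratio times the prior model
odds, 10:1 for neutrality by default). Proposal scales for the
random-walk updates of p, alpha, and beta are tuned in pilot runs
toward ~30% acceptance. Posterior inclusion probabilities P_i give
q-values as the running mean of (1 - P) down the ranked list; loci with
q < 0.05 are classified diversifying (alpha_mean > 0) or balancing
(alpha_mean < 0), alpha_mean being the posterior mean over iterations
in which the locus was included. Loci monomorphic across all
populations are excluded up front with a logged count. Default run
lengths mirror the reference tool (20 x 2000 pilot, 50k burn-in, 5k
samples at thinning 10); the short chains used throughout the tests
(5k burn-in, 2k samples) are enough for these data sizes because all
updates are vectorised across loci.

A quantitative caution established during development by exact
numerical integration of the model's own marginal likelihoods: with 5
populations of 40 alleles, a locus effect of |alpha| = 2 yields log
Bayes factors of only ~0-3.5, i.e. posterior inclusion below the ~0.95
needed for q < 0.05. Five-population panels simply cannot certify
moderate selection effects locus by locus at that FDR; what they can do
— and what the tests verify — is keep the neutral false-flag fraction
at or below 0.05 and recover the *sign* of planted effects (>= 90%).
This mirrors the original study's observation that its very high
background F_ST limited outlier detection. Stronger effects
(|alpha| >= 3.5, as planted in the pipeline demo) are flaggable.

Supporting per-locus QC: Weir–Cockerham (1984) F_ST from allele counts
(allele-level variance components; monomorphic loci undefined), the
closed-form exact Hardy–Weinberg test (conditional on allele counts,
summing heterozygote configurations no more probable than observed; an
MC mode exists for cross-checking), and a GENEPOP-style probability
test of linkage disequilibrium: a Metropolis chain over two-locus
genotype tables with fixed margins, batch means giving the p-value and
its standard error. Transect consistency intersects the outlier sets of
the global scan and each local (within-transect) scan; loci absent from
a subset scan (monomorphic there) cannot be consistent outliers.

## SNP tagging

A site is a SNP when at least two nucleotides are observed and the
rarer of the two best-covered alleles has coverage strictly greater
than 20 reads — a deep-coverage heuristic that suppresses sequencing
error without genotype likelihoods; indel evidence is ignored and
sites with three observed alleles are flagged. Tag SNPs are chosen per
gene (up to 2), ranked by rare-allele coverage with position as the
tiebreak; the ranking rule is a package convention since any choice of
tags is one.

## Synthetic data: what it does and does not emulate

The generators produce exactly the statistical structure the analyses
assume: GY94 evolution with i.i.d. site classes; an island model whose
likelihood is the outlier scan's own; HWE (or fixed-F) genotypes;
Poisson depth with uniform base-call errors. They do **not** emulate
alignment error, assembly artefacts, indels, linked selection,
isolation by distance, or spatially structured demography. Passing
calibration on these data therefore demonstrates internal correctness
— the estimators recover what the model generates — not robustness to
the model violations real transcriptome data contain; the QC filters
exist precisely because real data violate them.

Default conditions (chosen once, as study-like settings): 5 taxa with
terminal branches of 0.05–0.1 substitutions/codon and a 0.4–0.45
outgroup branch; kappa = 2; uniform codon frequencies in simulation;
5 populations x 20 diploids (40 alleles); background beta = -1.0,
anchored at the beta prior's mean (the study's own background, F_ST
0.6–0.9, corresponds to beta ~ +1 and is reproduced by passing beta
explicitly — at that level roughly a fifth of simulated loci fix and
are excluded as monomorphic); read simulation at 250x mean coverage
with error rate 1e-3.

## Problem sizes used in the shipped experiments

The test suite and `scripts/acceptance.py` run everything at sizes a
single core handles comfortably: likelihood-oracle checks on 3–4 taxa
and <= 5 sites; M0 recovery at 100–1000 codons over 10–20 seeds;
branch-site calibration on 200 null and 30 planted genes of 200–300
codons; outlier calibration on 100-locus, 5-population panels with
5000/2000-iteration chains; the end-to-end demo on 4–8 genes and 24–60
loci with 5–20 bootstrap replicates. Defaults in the library itself
(1000 bootstrap replicates, BayeScan-scale chain lengths) are the
full-study settings.
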
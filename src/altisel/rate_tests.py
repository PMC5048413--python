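"""Transcriptome-wide rate comparisons and category-level statistics.

Covers the "is the high-altitude lineage evolving faster?" layer of the
scan: bootstrap distributions of per-branch dN/dS from the concatenated
ortholog alignment, a paired exact binomial test between branches,
per-GO-category mean dN/dS with a resampling significance test,
hypergeometric over-representation of positively selected genes, and
Benjamini-Hochberg FDR control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import binom, hypergeom

from .alignment import CodonAlignment
from .codon_ml import FitResult, fit_branch
from .trees import Phylogeny

logger = logging.getLogger(__name__)

__all__ = [
    "BootstrapRateResult",
    "CategoryRate",
    "concatenate",
    "bootstrap_branch_rates",
    "binomial_rate_test",
    "category_rates",
    "enrichment_test",
    "bh_fdr",
    "read_annotation",
    "gene_category_edge_list",
]


@dataclass
class BootstrapRateResult:
    """Per-branch dN/dS vectors over bootstrap replicates."""

    omega: dict[str, np.ndarray]  # branch id -> replicate vector
    n_replicates: int
    seed: int
    n_failed: int = 0
    point_estimate: FitResult | None = None

    def __post_init__(self):
        lengths = {len(v) for v in self.omega.values()}
        if len(lengths) > 1:
            raise ValueError("replicate vectors differ in length")


@dataclass
class CategoryRate:
    category_id: str
    n_genes: int
    mean_omega: float
    p_value: float
    q_value: float = float("nan")


def concatenate(alignments: list[CodonAlignment]) -> CodonAlignment:
    """Column-wise concatenation of same-taxa gene alignments.

    Taxon sets must agree (rows are matched by taxon id, not order);
    the result records each gene's (start, end) codon interval.
    """
    if not alignments:
        raise ValueError("nothing to concatenate")
    taxa = list(alignments[0].taxon_ids)
    taxon_set = set(taxa)
    parts = {t: [] for t in taxa}
    boundaries = {}
    offset = 0
    for aln in alignments:
        if set(aln.taxon_ids) != taxon_set:
            raise ValueError(
                f"taxon set of {aln.gene_id!r} does not match the first gene"
            )
        for t in taxa:
            parts[t].append(aln.sequences[aln.taxon_ids.index(t)])
        boundaries[aln.gene_id] = (offset, offset + aln.n_codons)
        offset += aln.n_codons
    out = CodonAlignment(
        taxa,
        ["".join(parts[t]) for t in taxa],
        gene_id="concatenated",
    )
    out.gene_boundaries = boundaries
    return out


def bootstrap_branch_rates(
    aln: CodonAlignment,
    tree: Phylogeny,
    branch_partition: dict[str, str] | None = None,
    n_rep: int = 1000,
    seed: int = 0,
    resampler=None,
) -> BootstrapRateResult:
    """Bootstrap the per-branch dN/dS of the branch model.

    Each replicate resamples codon columns of the (concatenated)
    alignment with replacement and refits the branch model, warm-started
    from the full-data fit. `branch_partition` assigns branches to
    omega classes (default: one class per branch). `resampler`, if
    given, maps (rng, n_codons) -> column index array — the identity
    hook makes a single replicate reproduce the point estimate exactly.
    Deterministic in `seed`; replicates that fail to converge are
    recorded as missing (NaN) and counted.
    """
    if branch_partition is None:
        branch_partition = {b: b for b in tree.branches}
    point = fit_branch(aln, tree, branch_partition)
    vectors = {b: np.full(n_rep, np.nan) for b in tree.branches}
    n_failed = 0
    for rep in range(n_rep):
        rng = np.random.default_rng([seed, rep])
        if resampler is None:
            cols = rng.integers(0, aln.n_codons, size=aln.n_codons)
        else:
            cols = resampler(rng, aln.n_codons)
        baln = aln.take_columns(cols)
        fit = fit_branch(
            baln, tree, branch_partition, initial=point, max_sweeps=10
        )
        if not fit.converged:
            n_failed += 1
            continue
        for b in tree.branches:
            vectors[b][rep] = fit.omega_map[b]
    if n_failed:
        logger.warning("%d/%d bootstrap replicates failed to converge", n_failed, n_rep)
    return BootstrapRateResult(
        omega=vectors,
        n_replicates=n_rep,
        seed=seed,
        n_failed=n_failed,
        point_estimate=point,
    )


def binomial_rate_test(omega_high, omega_low) -> float:
    """Paired exact binomial test of a rate difference between branches.

    Counts the bootstrap replicates in which the putative fast branch
    has the larger dN/dS (ties count one half) and tests that count
    against Binomial(n, 1/2), two-sided; with a symmetric null the
    two-sided p equals the summed tails. NaN replicates (either side)
    are dropped in pairs.
    """
    high = np.asarray(omega_high, dtype=float)
    low = np.asarray(omega_low, dtype=float)
    if high.shape != low.shape:
        raise ValueError("replicate vectors must have equal length")
    keep = ~(np.isnan(high) | np.isnan(low))
    high, low = high[keep], low[keep]
    n = len(high)
    if n == 0:
        raise ValueError("no usable replicate pairs")
    k = float((high > low).sum()) + 0.5 * float((high == low).sum())
    lo = min(k, n - k)
    p = binom.cdf(np.floor(lo), n, 0.5) + binom.sf(np.ceil(n - lo) - 1, n, 0.5)
    return float(min(1.0, p))


def category_rates(
    per_gene_omega: dict[str, float],
    annotation: dict[str, set],
    min_genes: int = 5,
    n_boot: int = 1000,
    seed: int = 0,
) -> list[CategoryRate]:
    """Mean dN/dS per functional category, tested against the genome average.

    For each category with at least `min_genes` annotated genes in the
    universe, significance of "higher than average" comes from
    resampling same-size gene sets from the universe (upper-tail
    add-one p); q-values are Benjamini-Hochberg across categories.
    Categories below `min_genes` are skipped and logged.
    """
    universe = sorted(per_gene_omega)
    values = np.array([per_gene_omega[g] for g in universe])
    by_cat: dict[str, list[int]] = {}
    index = {g: i for i, g in enumerate(universe)}
    for gene, cats in annotation.items():
        if gene not in index:
            continue
        for cat in cats:
            by_cat.setdefault(cat, []).append(index[gene])
    rng = np.random.default_rng(seed)
    results = []
    for cat in sorted(by_cat):
        idx = by_cat[cat]
        if len(idx) < min_genes:
            logger.info("category %s below min_genes (%d)", cat, len(idx))
            continue
        observed = float(values[idx].mean())
        k = len(idx)
        if k == len(universe):
            p = 1.0  # the category IS the universe: cannot exceed itself
        else:
            boot = np.array(
                [
                    values[rng.choice(len(universe), size=k, replace=False)].mean()
                    for _ in range(n_boot)
                ]
            )
            p = (1.0 + float((boot >= observed).sum())) / (n_boot + 1.0)
        results.append(CategoryRate(cat, k, observed, p))
    qs = bh_fdr([r.p_value for r in results])
    for r, q in zip(results, qs):
        r.q_value = float(q)
    return results


def enrichment_test(
    psg_set, universe, annotation: dict[str, set]
) -> pd.DataFrame:
    """Hypergeometric over-representation of PSGs per functional term.

    For each term: k = PSGs annotated to it, K = universe genes
    annotated to it, n = PSGs, N = universe size; upper-tail p =
    P(X >= k); q by Benjamini-Hochberg across terms.
    """
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    psg_set = set(psg_set)
    if not psg_set <= universe:
        raise ValueError("psg_set must be a subset of the universe")
    terms: dict[str, set] = {}
    for gene, cats in annotation.items():
        if gene not in universe:
            continue
        for cat in cats:
            terms.setdefault(cat, set()).add(gene)
    n_univ = len(universe)
    n_psg = len(psg_set)
    rows = []
    for term in sorted(terms):
        genes = terms[term]
        k = len(genes & psg_set)
        big_k = len(genes)
        p = float(hypergeom.sf(k - 1, n_univ, big_k, n_psg))
        rows.append(
            {"term": term, "k": k, "K": big_k, "n": n_psg, "N": n_univ, "p": p}
        )
    df = pd.DataFrame(rows, columns=["term", "k", "K", "n", "N", "p"])
    df["q"] = bh_fdr(df["p"].to_numpy()) if len(df) else []
    return df


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone, q >= p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# annotation I/O
# ---------------------------------------------------------------------------


def read_annotation(path) -> dict[str, set]:
    """Read a gene-to-category map: gene_id, category_id[, name, namespace]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if "gene_id" not in df.columns or "category_id" not in df.columns:
        raise ValueError("annotation table needs gene_id and category_id columns")
    out: dict[str, set] = {}
    for row in df.itertuples(index=False):
        out.setdefault(str(row.gene_id), set()).add(str(row.category_id))
    return out


def gene_category_edge_list(genes, annotation: dict[str, set]) -> pd.DataFrame:
    """Bipartite gene-function edges for the given genes (e.g. PSGs)."""
    rows = [
        {"gene_id": g, "category_id": c}
        for g in sorted(genes)
        for c in sorted(annotation.get(g, ()))
    ]
    return pd.DataFrame(rows, columns=["gene_id", "category_id"])
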
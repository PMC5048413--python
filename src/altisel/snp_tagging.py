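"""SNP calling from per-site read counts and per-gene tag-SNP selection.

A site is called polymorphic only when the rarer of its two best-covered
alleles is itself seen on more than `min_rare_coverage` reads (default
20): at deep, pooled RNA-seq coverage this suppresses sequencing-error
artefacts without a genotype-likelihood model. Indel evidence is never
considered. Tag SNPs are then chosen per gene, ranked by rare-allele
coverage, for downstream population genotyping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


@dataclass
class ReadCountSite:
    """Read support per nucleotide at one transcript position (1-based)."""

    gene_id: str
    position: int
    allele_counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.position < 1:
            raise ValueError("position must be >= 1 (1-based)")
        if any(c < 0 for c in self.allele_counts.values()):
            raise ValueError("allele counts must be >= 0")


@dataclass
class TagSNP:
    gene_id: str
    position: int
    ref_allele: str
    alt_allele: str
    rare_allele_coverage: int
    triallelic: bool = False

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ValueError("ref and alt alleles must differ")


def call_snps(sites, min_rare_coverage: int = 20) -> list[TagSNP]:
    """Call biallelic SNPs where rare-allele coverage exceeds the cutoff.

    The two best-covered nucleotides form the candidate pair (a site
    with three observed alleles is flagged `triallelic`); the site is a
    SNP iff the rarer of the pair has coverage strictly greater than
    `min_rare_coverage`. Non-nucleotide evidence (indels) is ignored.
    """
    calls = []
    for site in sites:
        counts = [
            (site.allele_counts.get(b, 0), b)
            for b in BASES
            if site.allele_counts.get(b, 0) > 0
        ]
        if len(counts) < 2:
            continue
        # rank by coverage, ties broken alphabetically for determinism
        counts.sort(key=lambda t: (-t[0], t[1]))
        (major_n, major), (minor_n, minor) = counts[0], counts[1]
        if minor_n > min_rare_coverage:
            calls.append(
                TagSNP(
                    gene_id=site.gene_id,
                    position=site.position,
                    ref_allele=major,
                    alt_allele=minor,
                    rare_allele_coverage=minor_n,
                    triallelic=len(counts) > 2,
                )
            )
    return calls


def select_tag_snps(snps, max_per_gene: int = 2) -> list[TagSNP]:
    """Pick up to `max_per_gene` tag SNPs per gene.

    Ranking is by rare-allele coverage (descending), ties by position
    (ascending); output order is by gene then position. Genes without
    any called SNP are simply absent (and logged).
    """
    by_gene: dict[str, list[TagSNP]] = {}
    for snp in snps:
        by_gene.setdefault(snp.gene_id, []).append(snp)
    tags = []
    for gene in sorted(by_gene):
        ranked = sorted(
            by_gene[gene], key=lambda s: (-s.rare_allele_coverage, s.position)
        )
        tags.extend(sorted(ranked[:max_per_gene], key=lambda s: s.position))
    if not by_gene:
        logger.warning("no SNPs supplied; no tag SNPs selected")
    return tags


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_site_counts(path) -> list[ReadCountSite]:
    """Read a per-site count table: gene_id, position, A, C, G, T."""
    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"gene_id", "position", *BASES}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"site count table missing columns: {sorted(missing)}")
    return [
        ReadCountSite(
            gene_id=str(row.gene_id),
            position=int(row.position),
            allele_counts={b: int(getattr(row, b)) for b in BASES},
        )
        for row in df.itertuples(index=False)
    ]


def write_site_counts(sites, path, header_comment: str | None = None) -> None:
    rows = [
        {
            "gene_id": s.gene_id,
            "position": s.position,
            **{b: s.allele_counts.get(b, 0) for b in BASES},
        }
        for s in sites
    ]
    _write_tsv(pd.DataFrame(rows), path, header_comment)


def write_tag_snps(tags, path, header_comment: str | None = None) -> None:
    rows = [
        {
            "gene_id": t.gene_id,
            "position": t.position,
            "ref": t.ref_allele,
            "alt": t.alt_allele,
            "rare_allele_coverage": t.rare_allele_coverage,
            "triallelic": int(t.triallelic),
        }
        for t in tags
    ]
    _write_tsv(pd.DataFrame(rows), path, header_comment)


def tags_to_vcf(tags, path) -> None:
    """Minimal VCF export: CHROM = gene id, POS on the transcript."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=altisel\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for t in tags:
            fh.write(
                f"{t.gene_id}\t{t.position}\t{t.gene_id}_{t.position}\t"
                f"{t.ref_allele}\t{t.alt_allele}\t.\tPASS\t.\n"
            )


def _write_tsv(df: pd.DataFrame, path, header_comment: str | None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
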
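"""Codon-alignment quality control for selection scans.

dN/dS-based tests are sensitive to alignment artefacts: internal stop
codons betray frame errors or pseudogenes, very short alignments give
unstable estimates, gappy columns are unreliable, and saturation at
synonymous sites inflates dN/dS and with it the false-positive rate of
positive-selection tests. This module applies those filters in a fixed
order (validate, trim, saturation) and records per-gene reasons, using
the Nei-Gojobori (1986) counting estimator of dN and dS with the
Jukes-Cantor correction for the saturation check.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from itertools import permutations

import pandas as pd

from ._codons import STOP_CODONS, translate_codon
from .alignment import CodonAlignment

logger = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "FilterThresholds",
    "validate_codon_alignment",
    "trim_alignment",
    "ng86_pairwise",
    "saturation_filter",
    "filter_orthologs",
    "write_filter_reports",
]

_BASES = ("A", "C", "G", "T")


@dataclass
class FilterReport:
    """Why a gene was kept or dropped; retained iff no reasons."""

    gene_id: str
    retained: bool
    reasons: list[str] = field(default_factory=list)
    #: 1-based codon indices of offending columns, per reason, when known
    details: dict[str, list] = field(default_factory=dict)

    def __post_init__(self):
        if self.retained != (not self.reasons):
            raise ValueError("retained must be equivalent to an empty reason list")


@dataclass
class FilterThresholds:
    min_length_nt: int = 200
    max_gap_fraction: float = 0.0
    ds_cap: float = 3.0


def _is_clean(codon: str) -> bool:
    return all(c in _BASES for c in codon)


def validate_codon_alignment(
    aln: CodonAlignment, min_length_nt: int = 200
) -> FilterReport:
    """Flag internal stop codons and sub-minimum alignment length.

    A stop codon in the final column is treated as a legitimate
    terminator; anywhere else it is an ``internal_stop``. Alignments
    shorter than `min_length_nt` nucleotides are ``too_short``.
    """
    reasons = []
    details: dict[str, list] = {}
    stops = []
    n = aln.n_codons
    for row in range(aln.n_taxa):
        for col in range(n - 1):  # terminal column exempt
            if aln.codon(row, col) in STOP_CODONS:
                stops.append((aln.taxon_ids[row], col + 1))
    if stops:
        reasons.append("internal_stop")
        details["internal_stop"] = stops
    if aln.n_nucleotides < min_length_nt:
        reasons.append("too_short")
        details["too_short"] = [aln.n_nucleotides]
    return FilterReport(aln.gene_id, not reasons, reasons, details)


def trim_alignment(
    aln: CodonAlignment, max_gap_fraction: float = 0.0
) -> CodonAlignment:
    """Drop codon columns whose gap-or-ambiguity fraction is too high.

    A row's codon counts against a column when it contains any
    character outside {A, C, G, T}. With the default of 0 any column
    touched by a gap or N is removed. Column order is preserved and
    trimming is idempotent.
    """
    keep = []
    for col in range(aln.n_codons):
        dirty = sum(
            not _is_clean(aln.codon(row, col)) for row in range(aln.n_taxa)
        )
        if dirty / aln.n_taxa <= max_gap_fraction:
            keep.append(col)
    if not keep:
        raise ValueError(
            f"trimming removed every column of {aln.gene_id!r}"
        )
    if len(keep) == aln.n_codons:
        return aln
    return aln.take_columns(keep)


# ---------------------------------------------------------------------------
# NG86 counting estimator
# ---------------------------------------------------------------------------


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) potential sites of one codon.

    Each of the nine single-nucleotide neighbours contributes 1/3 of a
    site; changes creating a stop codon count as nonsynonymous. The two
    classes are normalised to sum to 3.
    """
    aa = translate_codon(codon)
    syn = nonsyn = 0
    for pos in range(3):
        for base in _BASES:
            if base == codon[pos]:
                continue
            neighbour = codon[:pos] + base + codon[pos + 1 :]
            if translate_codon(neighbour) == aa:
                syn += 1
            else:
                nonsyn += 1
    total = syn + nonsyn
    return 3 * syn / total, 3 * nonsyn / total


def _codon_differences(codon_a: str, codon_b: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) differences, averaged over pathways.

    Codons differing at several positions are connected by all orderings
    of single changes, weighted equally; each step is synonymous iff it
    preserves the amino acid (steps through stop codons are
    nonsynonymous).
    """
    diff = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff:
        return 0.0, 0.0
    syn = nonsyn = 0.0
    paths = list(permutations(diff))
    weight = 1.0 / len(paths)
    for path in paths:
        cur = codon_a
        for pos in path:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1 :]
            if translate_codon(cur) == translate_codon(nxt) and translate_codon(cur) != "*":
                syn += weight
            else:
                nonsyn += weight
            cur = nxt
    return syn, nonsyn


def ng86_pairwise(row_a, row_b) -> dict[str, float]:
    """Nei-Gojobori (1986) dN and dS between two codon sequences.

    Accepts two equal-length codon-string lists (or nucleotide strings);
    codon pairs where either member contains a gap or ambiguity are
    skipped. Proportions are corrected with the Jukes-Cantor formula;
    a synonymous proportion >= 3/4 is reported as dS = +inf
    (saturated). Symmetric in its arguments.
    """
    codons_a = _as_codons(row_a)
    codons_b = _as_codons(row_b)
    if len(codons_a) != len(codons_b):
        raise ValueError("sequences differ in codon length")
    syn_sites = nonsyn_sites = 0.0
    syn_diff = nonsyn_diff = 0.0
    n_used = 0
    for ca, cb in zip(codons_a, codons_b):
        if not (_is_clean(ca) and _is_clean(cb)):
            continue
        if ca in STOP_CODONS or cb in STOP_CODONS:
            continue
        n_used += 1
        for codon in (ca, cb):
            s, n = _codon_sites(codon)
            syn_sites += s / 2
            nonsyn_sites += n / 2
        sd, nd = _codon_differences(ca, cb)
        syn_diff += sd
        nonsyn_diff += nd
    if n_used == 0:
        raise ValueError("no comparable codon pairs")
    ps = syn_diff / syn_sites if syn_sites > 0 else 0.0
    pn = nonsyn_diff / nonsyn_sites if nonsyn_sites > 0 else 0.0
    return {
        "dN": _jukes_cantor(pn),
        "dS": _jukes_cantor(ps),
        "syn_sites": syn_sites,
        "nonsyn_sites": nonsyn_sites,
        "syn_diffs": syn_diff,
        "nonsyn_diffs": nonsyn_diff,
        "n_codons_compared": n_used,
    }


def _jukes_cantor(p: float) -> float:
    if p >= 0.75:
        return math.inf
    if p <= 0:
        return 0.0
    return -0.75 * math.log(1 - 4 * p / 3)


def _as_codons(row) -> list[str]:
    if isinstance(row, str):
        if len(row) % 3:
            raise ValueError("nucleotide string length not a multiple of 3")
        return [row[i : i + 3].upper() for i in range(0, len(row), 3)]
    return [str(c).upper() for c in row]


def saturation_filter(aln: CodonAlignment, ds_cap: float = 3.0) -> FilterReport:
    """Flag a gene whose synonymous sites are saturated in any pair.

    A pair is saturated when its NG86 dS is infinite (Jukes-Cantor
    undefined) or exceeds `ds_cap`; dN/dS from such genes is upward
    biased and would feed false positives into the selection tests.
    """
    if aln.n_taxa < 2:
        raise ValueError("need at least 2 rows")
    saturated_pairs = []
    for i in range(aln.n_taxa):
        for j in range(i + 1, aln.n_taxa):
            try:
                est = ng86_pairwise(aln.sequences[i], aln.sequences[j])
            except ValueError:
                continue  # no comparable codons: not evidence of saturation
            if est["dS"] > ds_cap:
                saturated_pairs.append((aln.taxon_ids[i], aln.taxon_ids[j]))
    if saturated_pairs:
        return FilterReport(
            aln.gene_id, False, ["saturated"], {"saturated": saturated_pairs}
        )
    return FilterReport(aln.gene_id, True)


def filter_orthologs(
    alignments, thresholds: FilterThresholds | None = None
) -> tuple[list[CodonAlignment], list[FilterReport]]:
    """Validate, trim, and saturation-test each gene, in that order.

    Returns the retained (trimmed) alignments and one report per input
    gene; a gene is retained iff it accumulated no flags. Reports
    partition the input: retained + rejected = input.
    """
    thresholds = thresholds or FilterThresholds()
    retained = []
    reports = []
    if not alignments:
        logger.warning("filter_orthologs called with no alignments")
    for aln in alignments:
        report = validate_codon_alignment(aln, thresholds.min_length_nt)
        reasons = list(report.reasons)
        details = dict(report.details)
        trimmed = None
        try:
            trimmed = trim_alignment(aln, thresholds.max_gap_fraction)
        except ValueError:
            reasons.append("excess_gaps")
            details["excess_gaps"] = ["all columns removed"]
        if trimmed is not None:
            sat = saturation_filter(trimmed, thresholds.ds_cap)
            reasons.extend(sat.reasons)
            details.update(sat.details)
        final = FilterReport(aln.gene_id, not reasons, reasons, details)
        reports.append(final)
        if final.retained:
            retained.append(trimmed)
    return retained, reports


def write_filter_reports(reports, path, header_comment: str | None = None) -> None:
    rows = [
        {
            "gene_id": r.gene_id,
            "retained": int(r.retained),
            "reasons": ",".join(r.reasons) if r.reasons else ".",
        }
        for r in reports
    ]
    df = pd.DataFrame(rows, columns=["gene_id", "retained", "reasons"])
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False)
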
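"""One-to-one ortholog inference by best reciprocal hits (BRH).

Two transcripts are called orthologs when each is the other's best
cross-species match and both supporting e-values pass the threshold
(default 1e-10). Hit tables normally come from an external translated
search (BLAST outfmt-6 tabular); for desk-scale fixtures a small
built-in translated aligner (six-frame translation + Smith-Waterman)
can produce them, with a crude Karlin-Altschul-style e-value that is a
stand-in for real search statistics, not a replacement for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Align import substitution_matrices
from Bio.Seq import Seq

__all__ = [
    "HitRecord",
    "OrthologPair",
    "six_frame_translate",
    "local_align_score",
    "best_reciprocal_hits",
    "assembly_stats",
    "read_blast_tabular",
    "write_ortholog_pairs",
    "translated_hit_table",
]

_VALID_NT = set("ACGTN")


@dataclass
class HitRecord:
    """One row of a similarity search: query, subject, score, e-value."""

    query_id: str
    subject_id: str
    bit_score: float
    e_value: float

    def __post_init__(self):
        if not self.query_id or not self.subject_id:
            raise ValueError("hit ids must be nonempty")
        if self.e_value < 0:
            raise ValueError("e-value must be >= 0")


@dataclass
class OrthologPair:
    id_a: str
    id_b: str
    hit_ab: HitRecord
    hit_ba: HitRecord
    #: True when the best hit in either direction was decided by the
    #: tie rule (equal bit scores) rather than by score alone
    tie_broken: bool = False


def six_frame_translate(sequence: str) -> dict[str, str]:
    """Translate a nucleotide sequence in all six reading frames.

    Returns frames ``+1..+3`` and ``-1..-3``; codons containing N
    translate to 'X' and stop codons to '*'. Trailing bases that do not
    complete a codon are dropped.
    """
    if not sequence:
        raise ValueError("cannot translate an empty sequence")
    seq = sequence.upper()
    bad = set(seq) - _VALID_NT
    if bad:
        raise ValueError(f"invalid nucleotides: {sorted(bad)}")
    frames = {}
    rc = str(Seq(seq).reverse_complement())
    for strand, s in (("+", seq), ("-", rc)):
        for offset in range(3):
            sub = s[offset : offset + 3 * ((len(s) - offset) // 3)]
            frames[f"{strand}{offset + 1}"] = str(Seq(sub).translate())
    return frames


def _make_aligner(matrix_name: str, gap_open: float, gap_extend: float):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load(matrix_name)
    aligner.open_gap_score = gap_open
    aligner.extend_gap_score = gap_extend
    return aligner


def local_align_score(
    peptide_a: str,
    peptide_b: str,
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
) -> float:
    """Smith-Waterman local alignment score with affine gaps.

    A gap of length L scores ``gap_open + (L - 1) * gap_extend``. The
    score of the empty alignment is 0, so the result is never negative.
    Residues absent from the substitution matrix raise an error.
    """
    if not peptide_a or not peptide_b:
        raise ValueError("peptides must be nonempty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = set(str(c) for c in aligner.substitution_matrix.alphabet)
    unknown = (set(peptide_a) | set(peptide_b)) - alphabet
    if unknown:
        raise ValueError(f"residues not in {matrix}: {sorted(unknown)}")
    # the empty local alignment scores 0, so the result is never negative
    return max(0.0, float(aligner.score(peptide_a, peptide_b)))


def _best_hits(hits: list[HitRecord]) -> tuple[dict[str, HitRecord], set[str]]:
    """Best subject per query; ties by lower e-value, then subject id.

    Returns the best-hit map and the set of queries whose winner was
    decided by a tie on bit score.
    """
    best: dict[str, HitRecord] = {}
    tied: set[str] = set()
    for hit in hits:
        cur = best.get(hit.query_id)
        if cur is None:
            best[hit.query_id] = hit
            continue
        key_new = (-hit.bit_score, hit.e_value, hit.subject_id)
        key_cur = (-cur.bit_score, cur.e_value, cur.subject_id)
        if hit.bit_score == cur.bit_score:
            tied.add(hit.query_id)
        if key_new < key_cur:
            best[hit.query_id] = hit
    return best, tied


def best_reciprocal_hits(
    hits_ab: list[HitRecord],
    hits_ba: list[HitRecord],
    e_threshold: float = 1e-10,
) -> list[OrthologPair]:
    """Mutual-best pairs with both e-values at or below the threshold.

    (a, b) is returned iff b is a's best subject in the A->B table AND
    a is b's best subject in the B->A table; each id therefore appears
    in at most one pair. Best = highest bit score, ties broken by
    lowest e-value then lexicographic subject id (and flagged).
    """
    best_ab, tied_ab = _best_hits(hits_ab)
    best_ba, tied_ba = _best_hits(hits_ba)
    pairs = []
    for a, hit in sorted(best_ab.items()):
        b = hit.subject_id
        back = best_ba.get(b)
        if back is None or back.subject_id != a:
            continue
        if hit.e_value > e_threshold or back.e_value > e_threshold:
            continue
        pairs.append(
            OrthologPair(
                id_a=a,
                id_b=b,
                hit_ab=hit,
                hit_ba=back,
                tie_broken=a in tied_ab or b in tied_ba,
            )
        )
    return pairs


def assembly_stats(transcript_lengths) -> dict[str, float]:
    """N50, transcript count, and mean length of an assembly.

    N50 is the length of the shortest transcript in the smallest set of
    longest transcripts that together cover at least half the total
    assembled bases.
    """
    lengths = sorted(int(x) for x in transcript_lengths)
    if not lengths:
        raise ValueError("empty length list")
    total = sum(lengths)
    acc = 0
    n50 = lengths[-1]
    for length in reversed(lengths):
        acc += length
        if 2 * acc >= total:
            n50 = length
            break
    return {
        "n_transcripts": len(lengths),
        "n50": n50,
        "mean_length": total / len(lengths),
    }


# ---------------------------------------------------------------------------
# built-in translated search (fixture-scale stand-in for tBlastx)
# ---------------------------------------------------------------------------

# ungapped BLOSUM62 Karlin-Altschul constants, used only to convert raw
# Smith-Waterman scores into comparable bit scores / pseudo e-values
_KA_LAMBDA = 0.318
_KA_K = 0.13


def translated_hit_table(
    queries: dict[str, str],
    subjects: dict[str, str],
    matrix: str = "BLOSUM62",
    gap_open: float = -11.0,
    gap_extend: float = -1.0,
    min_score: float = 25.0,
) -> list[HitRecord]:
    """All-vs-all translated similarity search over two transcript sets.

    Each query/subject nucleotide sequence is translated in six frames;
    the hit score is the best Smith-Waterman score over all frame
    pairs (stop-containing segments score through '*' penalties of the
    matrix). Scores convert to bit scores and e-values with ungapped
    Karlin-Altschul constants -- adequate for ranking desk-scale
    fixtures, not a substitute for a real search's statistics.
    """
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    q_frames = {q: list(six_frame_translate(s).values()) for q, s in queries.items()}
    s_frames = {t: list(six_frame_translate(s).values()) for t, s in subjects.items()}
    hits = []
    for q, qfs in q_frames.items():
        for t, tfs in s_frames.items():
            raw = 0.0
            for qf in qfs:
                for tf in tfs:
                    if not qf or not tf:
                        continue
                    raw = max(raw, aligner.score(qf, tf))
            if raw < min_score:
                continue
            bits = (_KA_LAMBDA * raw - math.log(_KA_K)) / math.log(2)
            space = len(queries[q]) * len(subjects[t]) / 9.0
            e_value = space * 2.0 ** (-bits)
            hits.append(HitRecord(q, t, round(bits, 2), e_value))
    return hits


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def read_blast_tabular(path) -> list[HitRecord]:
    """Parse BLAST outfmt-6 tabular output (12 standard columns).

    Only qseqid, sseqid, evalue and bitscore are consumed. Malformed
    rows raise a parse error naming the line number.
    """
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise ValueError(
                    f"{path}: line {lineno}: expected >= 12 tab-separated "
                    f"columns, got {len(fields)}"
                )
            try:
                hits.append(
                    HitRecord(
                        query_id=fields[0],
                        subject_id=fields[1],
                        e_value=float(fields[10]),
                        bit_score=float(fields[11]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: {exc}") from exc
    return hits


def read_fasta_dict(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_ortholog_pairs(pairs, path, header_comment: str | None = None) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        fh.write("id_a\tid_b\tevalue_ab\tevalue_ba\ttie_broken\n")
        for p in pairs:
            fh.write(
                f"{p.id_a}\t{p.id_b}\t{p.hit_ab.e_value:.3g}\t"
                f"{p.hit_ba.e_value:.3g}\t{int(p.tie_broken)}\n"
            )
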
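"""In-frame codon alignments: the unit of every selection test here."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from ._codons import GAP_STATE, encode_codon, decode_codon


@dataclass
class CodonAlignment:
    """Aligned coding sequences, stored row-major as codon strings.

    Rows must be equal length and a multiple of three nucleotides.
    Codons containing gaps or ambiguity codes are retained but treated
    as missing data by the likelihood machinery.
    """

    taxon_ids: list[str]
    sequences: list[str]
    gene_id: str = ""
    #: optional (start, end) codon intervals per source gene after concatenation
    gene_boundaries: dict = field(default_factory=dict)

    def __post_init__(self):
        if len(self.taxon_ids) != len(self.sequences):
            raise ValueError("taxon_ids and sequences differ in length")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValueError(f"rows of {self.gene_id!r} differ in length")
        if self.sequences and len(self.sequences[0]) % 3 != 0:
            raise ValueError(
                f"alignment length of {self.gene_id!r} not a multiple of 3"
            )
        self.sequences = [s.upper() for s in self.sequences]

    # -- basic geometry ----------------------------------------------

    @property
    def n_taxa(self) -> int:
        return len(self.taxon_ids)

    @property
    def n_codons(self) -> int:
        return len(self.sequences[0]) // 3 if self.sequences else 0

    @property
    def n_nucleotides(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def codon(self, row: int, col: int) -> str:
        return self.sequences[row][3 * col : 3 * col + 3]

    def row_codons(self, row: int) -> list[str]:
        s = self.sequences[row]
        return [s[i : i + 3] for i in range(0, len(s), 3)]

    # -- views --------------------------------------------------------

    def encode(self) -> np.ndarray:
        """(n_taxa, n_codons) int matrix of sense-codon indices; missing = -1."""
        out = np.empty((self.n_taxa, self.n_codons), dtype=np.int16)
        for i in range(self.n_taxa):
            row = self.sequences[i]
            for j in range(self.n_codons):
                codon = row[3 * j : 3 * j + 3]
                try:
                    out[i, j] = encode_codon(codon)
                except ValueError:
                    # internal stop: invalid for the model, mask as missing;
                    # validation reports it separately
                    out[i, j] = GAP_STATE
        return out

    def take_columns(self, columns) -> "CodonAlignment":
        """New alignment keeping the given codon columns, in the given order."""
        columns = list(columns)
        seqs = [
            "".join(s[3 * c : 3 * c + 3] for c in columns) for s in self.sequences
        ]
        return CodonAlignment(list(self.taxon_ids), seqs, gene_id=self.gene_id)

    @classmethod
    def from_encoded(
        cls, taxon_ids, matrix: np.ndarray, gene_id: str = ""
    ) -> "CodonAlignment":
        seqs = [
            "".join(
                decode_codon(int(x)) if x >= 0 else "---" for x in matrix[i]
            )
            for i in range(matrix.shape[0])
        ]
        return cls(list(taxon_ids), seqs, gene_id=gene_id)

    # -- FASTA I/O -----------------------------------------------------

    @classmethod
    def from_fasta(cls, path, gene_id: str = "") -> "CodonAlignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls(
            [r.id for r in records],
            [str(r.seq) for r in records],
            gene_id=gene_id or str(path),
        )

    def to_fasta(self, path) -> None:
        records = [
            SeqRecord(Seq(s), id=t, description="")
            for t, s in zip(self.taxon_ids, self.sequences)
        ]
        SeqIO.write(records, str(path), "fasta")
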
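"""Universal genetic code tables and codon-level lookups.

The 61 sense codons of the standard nuclear code are the state space of
every codon model in this package; the three stop codons (TAA, TAG, TGA)
carry zero frequency and never appear in simulated or accepted data.
"""

from __future__ import annotations

import itertools

import numpy as np

NUCLEOTIDES = "TCAG"

_CODON_TABLE = {}
_BASES = {
    "T": "F F L L S S S S Y Y * * C C * W".split(),
    "C": "L L L L P P P P H H Q Q R R R R".split(),
    "A": "I I I M T T T T N N K K S S R R".split(),
    "G": "V V V V A A A A D D E E G G G G".split(),
}
for _first, _aas in _BASES.items():
    for _i, (_second, _third) in enumerate(
        itertools.product(NUCLEOTIDES, NUCLEOTIDES)
    ):
        _CODON_TABLE[_first + _second + _third] = _aas[_i]

STOP_CODONS = tuple(sorted(c for c, a in _CODON_TABLE.items() if a == "*"))
SENSE_CODONS = tuple(sorted(c for c, a in _CODON_TABLE.items() if a != "*"))
N_SENSE = len(SENSE_CODONS)  # 61

CODON_INDEX = {c: i for i, c in enumerate(SENSE_CODONS)}
AMINO_ACIDS = tuple(_CODON_TABLE[c] for c in SENSE_CODONS)

GAP_STATE = -1  # encoding for a gap/ambiguous codon (missing data)

_PURINES = frozenset("AG")


def translate_codon(codon: str) -> str:
    """Amino acid (one letter, '*' for stop) for an unambiguous codon."""
    return _CODON_TABLE[codon]


def is_transition(a: str, b: str) -> bool:
    """True if the single-nucleotide change a<->b is a transition."""
    return (a in _PURINES) == (b in _PURINES)


def _build_pair_tables():
    """Boolean 61x61 tables describing single-step codon changes."""
    one_diff = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    transition = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    synonymous = np.zeros((N_SENSE, N_SENSE), dtype=bool)
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [k for k in range(3) if ci[k] != cj[k]]
            if len(diffs) != 1:
                continue
            k = diffs[0]
            one_diff[i, j] = True
            transition[i, j] = is_transition(ci[k], cj[k])
            synonymous[i, j] = AMINO_ACIDS[i] == AMINO_ACIDS[j]
    return one_diff, transition, synonymous


ONE_DIFF, IS_TRANSITION, IS_SYNONYMOUS = _build_pair_tables()


def encode_codon(codon: str) -> int:
    """Map a codon string to its sense-codon index; gaps/ambiguity -> GAP_STATE.

    Any codon containing a non-ACGT character (gap, N, IUPAC ambiguity) is
    treated as missing data. A stop codon is rejected: stops are invalid
    states for the models here and must be caught upstream by validation.
    """
    codon = codon.upper()
    idx = CODON_INDEX.get(codon)
    if idx is not None:
        return idx
    if codon in STOP_CODONS:
        raise ValueError(f"stop codon {codon!r} is not a valid model state")
    return GAP_STATE


def decode_codon(index: int) -> str:
    return SENSE_CODONS[index]
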
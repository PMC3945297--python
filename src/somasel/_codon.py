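"""Precomputed standard-genetic-code lookup tables.

Everything downstream (site counting, substitution classification, cohort
simulation) is driven by the integer-coded tables built here, so the genetic
code is materialised exactly once, from Biopython's standard DNA codon table
(translation table 1).
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}

STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: codon string -> one-letter amino acid, with '*' for the three stops.
CODON_TO_AA: dict[str, str] = dict(standard_dna_table.forward_table)
for _stop in STOP_CODONS:
    CODON_TO_AA[_stop] = "*"

# Effect codes used in the integer tables below.
EFFECT_SYNONYMOUS = 0
EFFECT_MISSENSE = 1
EFFECT_NONSENSE = 2
_NO_CHANGE = -1

ALL_CODONS = tuple(a + b + c for a in BASES for b in BASES for c in BASES)


def codon_index(codon: str) -> int:
    """Map an unambiguous codon to its 0..63 index (A=0, C=1, G=2, T=3)."""
    return (
        BASE_INDEX[codon[0]] * 16 + BASE_INDEX[codon[1]] * 4 + BASE_INDEX[codon[2]]
    )


#: amino acid (or '*') per codon index.
AA64 = np.array([CODON_TO_AA[c] for c in ALL_CODONS])

#: True for TAA/TAG/TGA.
IS_STOP64 = np.array([c in STOP_CODONS for c in ALL_CODONS])

#: EFFECT64[codon, pos, alt_base] = effect code of the single-base change,
#: or -1 where alt equals the original base.  Stop codons keep -1 rows.
EFFECT64 = np.full((64, 3, 4), _NO_CHANGE, dtype=np.int8)

#: MUTANT64[codon, pos, alt_base] = index of the mutated codon.
MUTANT64 = np.zeros((64, 3, 4), dtype=np.int8)

for _ci, _codon in enumerate(ALL_CODONS):
    for _pos in range(3):
        for _alt in range(4):
            _mut = list(_codon)
            _mut[_pos] = BASES[_alt]
            _mi = codon_index("".join(_mut))
            MUTANT64[_ci, _pos, _alt] = _mi
            if BASES[_alt] == _codon[_pos] or _codon in STOP_CODONS:
                continue
            _aa, _maa = CODON_TO_AA[_codon], CODON_TO_AA["".join(_mut)]
            if _maa == "*":
                EFFECT64[_ci, _pos, _alt] = EFFECT_NONSENSE
            elif _maa == _aa:
                EFFECT64[_ci, _pos, _alt] = EFFECT_SYNONYMOUS
            else:
                EFFECT64[_ci, _pos, _alt] = EFFECT_MISSENSE

# Per-codon tallies over the 9 possible single-base changes.
SYN_CHANGES64 = (EFFECT64 == EFFECT_SYNONYMOUS).sum(axis=(1, 2)).astype(np.int64)
MISSENSE_CHANGES64 = (EFFECT64 == EFFECT_MISSENSE).sum(axis=(1, 2)).astype(np.int64)
NONSENSE_CHANGES64 = (EFFECT64 == EFFECT_NONSENSE).sum(axis=(1, 2)).astype(np.int64)
NONSYN_CHANGES64 = MISSENSE_CHANGES64 + NONSENSE_CHANGES64

#: MISSENSE_ALT_AAS[codon] = tuple of (alt amino acid, multiplicity) pairs,
#: one per distinct amino acid reachable by a single missense base change.
MISSENSE_ALT_AAS: tuple[tuple[tuple[str, int], ...], ...] = tuple(
    tuple(
        sorted(
            {
                aa: int(n)
                for aa, n in zip(
                    *np.unique(
                        AA64[MUTANT64[ci][EFFECT64[ci] == EFFECT_MISSENSE]],
                        return_counts=True,
                    )
                )
            }.items()
        )
    )
    for ci in range(64)
)


def encode_cds(cds: str) -> np.ndarray:
    """Encode a CDS into base indices; ambiguity codes become -1."""
    arr = np.frombuffer(cds.encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int8)
    for base, idx in BASE_INDEX.items():
        out[arr == ord(base)] = idx
    return out
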
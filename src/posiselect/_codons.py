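"""Codon-state tables shared by the substitution model and the simulator.

The 61 sense codons of the standard genetic code are indexed alphabetically
(AAA=0 ... TTT=60, stops removed).  Pairs of codons differing at exactly one
nucleotide position are precomputed together with whether the change is a
transition and whether it is nonsynonymous; these index arrays are all the
GY94-type generator construction needs.
"""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCS = "ACGT"
STOP_CODONS = frozenset(standard_dna_table.stop_codons)

#: the 61 sense codons, alphabetical
CODONS: tuple[str, ...] = tuple(
    "".join(c) for c in itertools.product(NUCS, repeat=3) if "".join(c) not in STOP_CODONS
)
CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(CODONS)}
N_STATES = len(CODONS)  # 61

#: amino acid of each sense codon
CODON_AA: tuple[str, ...] = tuple(standard_dna_table.forward_table[c] for c in CODONS)

_PURINES = {"A", "G"}


def _is_transition(x: str, y: str) -> bool:
    return (x in _PURINES) == (y in _PURINES)


def _pair_structure():
    ii, jj, trans, nonsyn = [], [], [], []
    for i, ci in enumerate(CODONS):
        for j, cj in enumerate(CODONS):
            if i >= j:
                continue
            diffs = [(a, b) for a, b in zip(ci, cj) if a != b]
            if len(diffs) != 1:
                continue
            ii.append(i)
            jj.append(j)
            trans.append(_is_transition(*diffs[0]))
            nonsyn.append(CODON_AA[i] != CODON_AA[j])
    return (
        np.asarray(ii, dtype=np.intp),
        np.asarray(jj, dtype=np.intp),
        np.asarray(trans, dtype=bool),
        np.asarray(nonsyn, dtype=bool),
    )


#: single-nucleotide-step codon pairs (i<j) with transition / nonsynonymous flags
PAIR_I, PAIR_J, PAIR_TRANSITION, PAIR_NONSYN = _pair_structure()


def translate_codon(codon: str) -> str:
    """Amino acid for a sense codon, '*' for a stop, 'X' otherwise (e.g. with N)."""
    codon = codon.upper()
    if codon in CODON_INDEX:
        return CODON_AA[CODON_INDEX[codon]]
    if codon in STOP_CODONS:
        return "*"
    return "X"


def codons_of(cds: str) -> list[str]:
    """Split a CDS into codons (length must be a multiple of 3)."""
    if len(cds) % 3:
        raise ValueError("CDS length not a multiple of 3")
    return [cds[i : i + 3] for i in range(0, len(cds), 3)]


def encode_codon(codon: str) -> int:
    """Codon state index, or -1 for gaps / N-containing codons (missing data)."""
    return CODON_INDEX.get(codon.upper(), -1)
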
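"""Standard genetic code tables shared by the codon machinery.

Everything is derived once, at import time, from Biopython's standard DNA
codon table, so the 61 sense codons, their amino acids, and the
single-nucleotide neighbor structure (used to build GY94-style rate
matrices) stay consistent with the standard code.
"""

from __future__ import annotations

import numpy as np
from Bio.Data.CodonTable import standard_dna_table

NUCLEOTIDES = "ACGT"
PURINES = {"A", "G"}

#: the 61 sense codons of the standard code, in lexicographic (ACGT) order
SENSE_CODONS: tuple[str, ...] = tuple(
    sorted(c for c in standard_dna_table.forward_table)
)
N_CODONS = len(SENSE_CODONS)  # 61

CODON_INDEX: dict[str, int] = {c: i for i, c in enumerate(SENSE_CODONS)}
STOP_CODONS: frozenset[str] = frozenset(standard_dna_table.stop_codons)

#: one-letter amino acid per sense codon (index-aligned with SENSE_CODONS)
CODON_AA: tuple[str, ...] = tuple(
    standard_dna_table.forward_table[c] for c in SENSE_CODONS
)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}

#: a deterministic representative codon per amino acid (first in ACGT order)
AA_TO_CODON: dict[str, str] = {}
for _c, _a in zip(SENSE_CODONS, CODON_AA):
    AA_TO_CODON.setdefault(_a, _c)


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES) == (b in PURINES)


def _neighbor_structure():
    """Arrays describing single-nucleotide codon moves i -> j.

    Returns (i_idx, j_idx, pos, target_nt, is_ts, is_nonsyn) over all ordered
    pairs of sense codons differing at exactly one position.
    """
    ii, jj, pos, tgt, ts, nonsyn = [], [], [], [], [], []
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diff = [k for k in range(3) if ci[k] != cj[k]]
            if len(diff) != 1:
                continue
            k = diff[0]
            ii.append(i)
            jj.append(j)
            pos.append(k)
            tgt.append(NUCLEOTIDES.index(cj[k]))
            ts.append(_is_transition(ci[k], cj[k]))
            nonsyn.append(CODON_AA[i] != CODON_AA[j])
    return (
        np.array(ii, dtype=np.intp),
        np.array(jj, dtype=np.intp),
        np.array(pos, dtype=np.intp),
        np.array(tgt, dtype=np.intp),
        np.array(ts, dtype=bool),
        np.array(nonsyn, dtype=bool),
    )


(NB_I, NB_J, NB_POS, NB_TARGET_NT, NB_IS_TS, NB_IS_NONSYN) = _neighbor_structure()

#: nucleotide composition of each sense codon: (61, 3) ints into NUCLEOTIDES
CODON_NT = np.array(
    [[NUCLEOTIDES.index(n) for n in c] for c in SENSE_CODONS], dtype=np.intp
)


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a sense codon; raises KeyError for stops."""
    return standard_dna_table.forward_table[codon]


def codon_frequencies_f3x4(nt_freqs_by_pos: np.ndarray) -> np.ndarray:
    """F3x4 codon frequencies from (3, 4) position-specific nucleotide freqs.

    Products over the three codon positions, stops excluded, renormalized.
    """
    nt = np.asarray(nt_freqs_by_pos, dtype=float)
    if nt.shape != (3, 4):
        raise ValueError("expected (3, 4) nucleotide frequency array")
    pi = nt[0, CODON_NT[:, 0]] * nt[1, CODON_NT[:, 1]] * nt[2, CODON_NT[:, 2]]
    s = pi.sum()
    if s <= 0:
        raise ValueError("degenerate nucleotide frequencies")
    return pi / s


def uniform_codon_frequencies() -> np.ndarray:
    return np.full(N_CODONS, 1.0 / N_CODONS)
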
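"""Shared fixtures: tiny trees, toy alignments, and paper-motif datasets."""

from __future__ import annotations

import numpy as np
import pytest

from rh1coev.genetic_code import AA_TO_CODON, CODON_INDEX
from rh1coev.io_core import CodonAlignment
from rh1coev.trees import CladeTree


def codon_aln_from_aa(
    rows: dict[str, str], ref_start: int = 1, ref_map=None
) -> CodonAlignment:
    """Codon alignment using a fixed representative codon per amino acid."""
    taxa = list(rows)
    codes = np.array(
        [
            [
                CODON_INDEX[AA_TO_CODON[a]] if a != "-" else -1
                for a in seq
            ]
            for seq in rows.values()
        ],
        dtype=np.int64,
    )
    if ref_map is None:
        ref_map = np.arange(ref_start, ref_start + codes.shape[1])
    return CodonAlignment(taxa=taxa, codes=codes, ref_map=np.asarray(ref_map))


@pytest.fixture
def quartet_tree() -> CladeTree:
    return CladeTree.from_newick(
        "((a:0.1,b:0.15):0.05,(c:0.2,d:0.1):0.08);"
    )


@pytest.fixture
def triplet_tree() -> CladeTree:
    return CladeTree.from_newick("((a:0.12,b:0.3):0.08,c:0.25);")


# Residues at sites 119/122/123/124 for the tetrapod rows of the published
# variation table, plus a conserved background of consensus-motif (LEIA)
# taxa standing in for the many invariant tetrapods the table omits.
TETRAPOD_MOTIFS = {
    "armadillo": "IEIA",
    "big_brown_bat": "LEVA",
    "cape_golden_mole": "MEIA",
    "common_shrew": "LEVA",
    "tree_shrew": "LEVA",
    "ground_squirrel": "LEVA",
    "brown_rat": "LEIG",
    "tasmanian_devil": "TEVA",
    "am_alligator": "LEVA",
    "cn_alligator": "LEVA",
    "anole": "LEMG",
    "python": "LEMA",
    "tiger_salamander": "MEIA",
    "fire_belly_newt": "LEIG",
    "frog_tropicalis": "LEMA",
    "frog_laevis": "LEVA",
}


@pytest.fixture
def tetrapod_site_alignment() -> CodonAlignment:
    rows = dict(TETRAPOD_MOTIFS)
    for k in range(12):  # conserved consensus background
        rows[f"conserved_{k}"] = "LEIA"
    return codon_aln_from_aa(rows, ref_map=[119, 122, 123, 124])
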
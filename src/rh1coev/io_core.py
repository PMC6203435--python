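"""Codon alignment container, FASTA I/O, pruning, and per-site summaries.

All user-facing site indices are reference residue numbers (bovine RH1
numbering by convention); internal column indices are 0-based.  Codon states
are indices into the 61 sense codons of the standard genetic code; gaps and
ambiguous triplets are coded -1 and treated as missing throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .genetic_code import (
    AMINO_ACIDS,
    CODON_AA,
    CODON_INDEX,
    SENSE_CODONS,
    STOP_CODONS,
)
from .trees import CladeTree

GAP = -1


@dataclass
class CodonAlignment:
    """Aligned in-frame coding sequences as codon columns.

    ``codes`` is an (n_taxa, n_sites) int array of sense-codon indices, -1
    for gap/missing.  ``ref_map`` maps column index -> reference residue
    number and is strictly increasing.
    """

    taxa: list[str]
    codes: np.ndarray
    ref_map: np.ndarray
    all_gap_columns: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.codes = np.asarray(self.codes, dtype=np.int64)
        self.ref_map = np.asarray(self.ref_map, dtype=np.int64)
        if len(self.taxa) != len(set(self.taxa)):
            raise ValueError("duplicate taxon labels")
        if self.codes.ndim != 2 or self.codes.shape[0] != len(self.taxa):
            raise ValueError("codes must be (n_taxa, n_sites)")
        if self.ref_map.shape != (self.codes.shape[1],):
            raise ValueError("ref_map must cover every column")
        if np.any(np.diff(self.ref_map) <= 0):
            raise ValueError("ref_map must be strictly increasing")
        if self.all_gap_columns is None:
            self.all_gap_columns = np.all(self.codes == GAP, axis=0)

    # ------------------------------------------------------------- views
    @property
    def n_taxa(self) -> int:
        return len(self.taxa)

    @property
    def n_sites(self) -> int:
        return self.codes.shape[1]

    def column_of_site(self, site: int) -> int:
        hits = np.nonzero(self.ref_map == site)[0]
        if hits.size == 0:
            raise KeyError(f"site {site} not in reference map")
        return int(hits[0])

    def codon_strings(self, taxon_index: int) -> str:
        return "".join(
            SENSE_CODONS[c] if c >= 0 else "---"
            for c in self.codes[taxon_index]
        )

    def aa_matrix(self) -> np.ndarray:
        """(n_taxa, n_sites) amino-acid indices into AMINO_ACIDS, -1 = gap."""
        lut = np.array([AMINO_ACIDS.index(a) for a in CODON_AA], dtype=np.int64)
        out = np.full(self.codes.shape, GAP, dtype=np.int64)
        mask = self.codes >= 0
        out[mask] = lut[self.codes[mask]]
        return out

    def subset_columns(self, cols) -> "CodonAlignment":
        cols = np.asarray(cols, dtype=np.intp)
        return CodonAlignment(
            taxa=list(self.taxa),
            codes=self.codes[:, cols],
            ref_map=self.ref_map[cols],
        )

    def restrict_to_sites(self, first: int, last: int) -> "CodonAlignment":
        """Explicit residue-number range restriction (inclusive)."""
        mask = (self.ref_map >= first) & (self.ref_map <= last)
        if not mask.any():
            raise ValueError("empty site range")
        return self.subset_columns(np.nonzero(mask)[0])


# ------------------------------------------------------------------ FASTA
def _encode_sequence(seq: str, label: str) -> np.ndarray:
    if len(seq) % 3 != 0:
        raise ValueError(f"{label}: length {len(seq)} not divisible by 3")
    n = len(seq) // 3
    out = np.full(n, GAP, dtype=np.int64)
    for k in range(n):
        codon = seq[3 * k : 3 * k + 3].upper().replace("U", "T")
        if codon in CODON_INDEX:
            out[k] = CODON_INDEX[codon]
        elif codon in STOP_CODONS:
            if k != n - 1:
                raise ValueError(
                    f"{label}: internal stop codon {codon} at codon {k + 1}"
                )
            out[k] = GAP  # terminal stop tolerated, treated as missing
        elif set(codon) <= set("ACGTN-?."):
            out[k] = GAP
        else:
            raise ValueError(f"{label}: unrecognized codon {codon!r}")
    return out


def read_codon_alignment(path: str | Path, ref_start: int = 1) -> CodonAlignment:
    """Read an in-frame codon FASTA; columns numbered from ``ref_start``."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    labels = [r.id for r in records]
    if len(labels) != len(set(labels)):
        raise ValueError("duplicate taxon labels")
    rows = [_encode_sequence(str(r.seq), r.id) for r in records]
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError("sequences differ in codon length")
    codes = np.stack(rows)
    n_sites = codes.shape[1]
    ref_map = np.arange(ref_start, ref_start + n_sites, dtype=np.int64)
    return CodonAlignment(taxa=labels, codes=codes, ref_map=ref_map)


def write_codon_alignment(aln: CodonAlignment, path: str | Path) -> None:
    records = [
        SeqRecord(Seq(aln.codon_strings(i)), id=t, description="")
        for i, t in enumerate(aln.taxa)
    ]
    SeqIO.write(records, str(path), "fasta")


def write_aa_alignment(aln: CodonAlignment, path: str | Path) -> None:
    aa = aln.aa_matrix()
    records = []
    for i, t in enumerate(aln.taxa):
        s = "".join(AMINO_ACIDS[a] if a >= 0 else "-" for a in aa[i])
        records.append(SeqRecord(Seq(s), id=t, description=""))
    SeqIO.write(records, str(path), "fasta")


# ------------------------------------------------------------------ prune
def prune_to_taxa(
    aln: CodonAlignment, tree: CladeTree, keep
) -> tuple[CodonAlignment, CladeTree]:
    """Restrict alignment rows and tree leaves to ``keep``.

    Degree-2 internal nodes are suppressed with branch lengths summed, so
    patristic distances among retained leaves are preserved.  Columns that
    become all-gap are retained but flagged in ``all_gap_columns``.
    """
    keep = set(keep)
    unknown = keep - set(aln.taxa)
    if unknown:
        raise ValueError(f"unknown taxa: {sorted(unknown)}")
    if not keep:
        raise ValueError("keep must be nonempty")
    new_tree = tree.pruned_to(keep)  # raises for <2 taxa
    rows = [i for i, t in enumerate(aln.taxa) if t in keep]
    new_aln = CodonAlignment(
        taxa=[aln.taxa[i] for i in rows],
        codes=aln.codes[rows],
        ref_map=aln.ref_map.copy(),
    )
    return new_aln, new_tree


# --------------------------------------------------------------- summaries
def site_variant_profile(aln: CodonAlignment, sites) -> pd.DataFrame:
    """Amino-acid frequencies per reference site (gaps excluded).

    Returns a tidy frame (site, residue, frequency, count, consensus flag);
    consensus = most frequent residue, ties broken alphabetically.
    """
    aa = aln.aa_matrix()
    rows = []
    for site in sites:
        col = aa[:, aln.column_of_site(site)]
        valid = col[col >= 0]
        if valid.size == 0:
            raise ValueError(f"site {site}: column entirely gapped")
        counts = np.bincount(valid, minlength=len(AMINO_ACIDS))
        total = counts.sum()
        # ties: alphabetical one-letter code == lowest index
        consensus_idx = int(np.argmax(counts))
        for idx in np.nonzero(counts)[0]:
            rows.append(
                {
                    "site": site,
                    "residue": AMINO_ACIDS[idx],
                    "count": int(counts[idx]),
                    "frequency": counts[idx] / total,
                    "is_consensus": idx == consensus_idx,
                }
            )
    return pd.DataFrame(rows)


def site_consensus(aln: CodonAlignment, site: int) -> str:
    prof = site_variant_profile(aln, [site])
    return prof.loc[prof["is_consensus"], "residue"].iloc[0]


@dataclass
class BinaryTraitVector:
    """Consensus-vs-variant coding of one alignment column.

    0 = consensus residue, 1 = natural variant, None = gap/missing.
    """

    site: int
    consensus: str
    taxa: list[str]
    values: list  # 0 | 1 | None

    def as_dict(self) -> dict:
        return dict(zip(self.taxa, self.values))

    @property
    def n_variant(self) -> int:
        return sum(1 for v in self.values if v == 1)

    @property
    def is_testable(self) -> bool:
        states = {v for v in self.values if v is not None}
        return states == {0, 1}


def encode_binary_trait(aln: CodonAlignment, site: int) -> BinaryTraitVector:
    aa = aln.aa_matrix()
    col = aa[:, aln.column_of_site(site)]
    if np.all(col < 0):
        raise ValueError(f"site {site}: column entirely gapped")
    consensus = site_consensus(aln, site)
    cons_idx = AMINO_ACIDS.index(consensus)
    values = [
        None if c < 0 else (0 if c == cons_idx else 1) for c in col
    ]
    return BinaryTraitVector(
        site=site, consensus=consensus, taxa=list(aln.taxa), values=values
    )
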
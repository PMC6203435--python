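"""Inter-residue distances from a structure file and focal-site neighborhoods.

Distances are minimum Euclidean distances over all heavy-atom (non-hydrogen)
pairs of two residues, the convention most consistent with published
contact distances for the metarhodopsin-II structure.  Only the first
alternate location of each atom is used.  The focal-site neighborhood is
the set of residues whose minimum distance is within a radius (6 Å by
default — the range of direct Van der Waals/hydrophobic contact), plus the
focal site's immediate sequence neighbors, whose distances are recorded
separately because covalent adjacency is not a through-space contact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import gemmi
import numpy as np
import pandas as pd


@dataclass
class ResidueDistanceMap:
    structure_id: str
    chain: str
    distances: dict = field(default_factory=dict)  # (res_i, res_j) -> Å
    radius: float = 6.0

    def get(self, i: int, j: int) -> float | None:
        if i == j:
            return 0.0
        return self.distances.get((min(i, j), max(i, j)))


def load_structure(path: str | Path) -> gemmi.Structure:
    st = gemmi.read_structure(str(path))
    st.setup_entities()
    return st


def _heavy_atom_coords(
    structure: gemmi.Structure, chain: str, resnum: int
) -> np.ndarray:
    model = structure[0]
    ch = model.find_chain(chain)
    if ch is None:
        raise KeyError(f"chain {chain!r} not in structure")
    coords = []
    for res in ch:
        if res.seqid.num != resnum:
            continue
        for atom in res:
            if atom.element.is_hydrogen:
                continue
            if atom.altloc not in ("", "\0", "A"):
                continue  # first alternate location only
            coords.append([atom.pos.x, atom.pos.y, atom.pos.z])
    if not coords:
        raise KeyError(f"residue {resnum} has no heavy atoms in chain {chain}")
    return np.asarray(coords)


def min_residue_distance(
    structure: gemmi.Structure | str | Path,
    chain: str,
    res_i: int,
    res_j: int,
) -> float:
    """Minimum heavy-atom distance in Å between two residues."""
    if not isinstance(structure, gemmi.Structure):
        structure = load_structure(structure)
    if res_i == res_j:
        return 0.0
    a = _heavy_atom_coords(structure, chain, res_i)
    b = _heavy_atom_coords(structure, chain, res_j)
    d2 = ((a[:, None, :] - b[None, :, :]) ** 2).sum(axis=2)
    return float(np.sqrt(d2.min()))


def residue_numbers(structure: gemmi.Structure, chain: str) -> list[int]:
    ch = structure[0].find_chain(chain)
    if ch is None:
        raise KeyError(f"chain {chain!r} not in structure")
    out = []
    for res in ch:
        if any(not at.element.is_hydrogen for at in res):
            if res.seqid.num not in out:
                out.append(res.seqid.num)
    return out


def neighborhood(
    structure: gemmi.Structure | str | Path,
    chain: str,
    focal: int = 122,
    radius: float = 6.0,
    include_sequence_neighbors: int = 2,
) -> ResidueDistanceMap:
    """Residues within ``radius`` Å of the focal residue (focal excluded).

    ``include_sequence_neighbors`` adds focal±1..k to the scan set even if
    their through-space distance is missing or above the radius; their
    distances (when computable) are still recorded.
    """
    if not isinstance(structure, gemmi.Structure):
        structure = load_structure(structure)
    resnums = residue_numbers(structure, chain)
    if focal not in resnums:
        raise KeyError(f"focal residue {focal} not in chain {chain}")
    rmap = ResidueDistanceMap(
        structure_id=structure.name or "structure", chain=chain, radius=radius
    )
    focal_xyz = _heavy_atom_coords(structure, chain, focal)
    for r in resnums:
        if r == focal:
            continue
        other = _heavy_atom_coords(structure, chain, r)
        d2 = ((focal_xyz[:, None, :] - other[None, :, :]) ** 2).sum(axis=2)
        rmap.distances[(min(focal, r), max(focal, r))] = float(np.sqrt(d2.min()))
    return rmap


def neighborhood_sites(rmap: ResidueDistanceMap, focal: int = 122,
                       include_sequence_neighbors: int = 2) -> set[int]:
    within = {
        (j if i == focal else i)
        for (i, j), d in rmap.distances.items()
        if focal in (i, j) and d <= rmap.radius
    }
    for k in range(1, include_sequence_neighbors + 1):
        within |= {focal - k, focal + k}
    within.discard(focal)
    return within


def distance_table(
    rmap: ResidueDistanceMap, focal: int = 122,
    include_sequence_neighbors: int = 2,
) -> pd.DataFrame:
    """Scan-set table: residue, distance (0.1 Å), within-radius flag."""
    sites = sorted(
        neighborhood_sites(rmap, focal, include_sequence_neighbors)
    )
    rows = []
    for s in sites:
        d = rmap.get(focal, s)
        rows.append(
            {
                "site": s,
                "focal": focal,
                "distance_A": None if d is None else round(d, 1),
                "within_radius": (d is not None) and d <= rmap.radius,
                "sequence_neighbor": abs(s - focal) <= include_sequence_neighbors,
            }
        )
    return pd.DataFrame(rows)


def write_toy_pdb(path: str | Path, residues: dict, chain: str = "A") -> None:
    """Write a minimal single-chain PDB from {resnum: [(element, xyz), ...]}.

    Intended for synthetic test structures; coordinates in Å.
    """
    lines = []
    serial = 1
    for resnum in sorted(residues):
        for k, (element, (x, y, z)) in enumerate(residues[resnum], start=1):
            name = f"{element}{k}"
            lines.append(
                f"ATOM  {serial:5d} {name:<4s} ALA {chain}{resnum:4d}    "
                f"{x:8.3f}{y:8.3f}{z:8.3f}  1.00  0.00          "
                f"{element:>2s}"
            )
            serial += 1
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")
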
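"""Synthetic-data generators with known ground truth for every pipeline stage.

Everything is a pure function of its parameters and a seed: codon
alignments evolved along a tree under site-class ω mixtures (with optional
clade-specific ω shifts), planted covarying column pairs, correlated binary
trait pairs, retinal-release traces, and A1-template absorbance spectra.
The default benchmark tree is a 30-taxon balanced tree of unit height split
into two named clades, mimicking a teleost/tetrapod partition at desk
scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .codon_models import (
    SiteClassModelSpec,
    _mixture_from_spec,
    mixture_transition_matrices,
)
from .correlated_evo import expand_independent_rates, simulate_joint_traits
from .genetic_code import AA_TO_CODON, CODON_AA, CODON_INDEX, N_CODONS
from .io_core import (
    BinaryTraitVector,
    CodonAlignment,
    write_codon_alignment,
)
from .photochem import a1_template
from .trees import CladeTree, TreeArrays, two_clade_tree


@dataclass
class SimSpec:
    """Ground-truth conditions for a synthetic benchmark dataset."""

    seed: int = 0
    n_taxa: int = 30
    tree_height: float = 1.0
    n_sites: int = 300
    kappa: float = 2.0
    model: SiteClassModelSpec | None = None
    planted_pairs: list = field(default_factory=list)  # [(site_i, site_j, coupling, noise)]
    clade_shift: dict | None = None  # partition name -> omega_d
    trait_rates: tuple = (1.0, 1.0, 1.0, 1.0)
    release_noise_sd: float = 0.02
    spectrum_noise_sd: float = 0.02


def default_m0_spec(omega: float = 0.2) -> SiteClassModelSpec:
    return SiteClassModelSpec(
        "M0", np.array([1.0]), class_omegas=np.array([omega])
    )


def simulate_codon_alignment(
    tree: CladeTree,
    model: SiteClassModelSpec,
    n_sites: int,
    *,
    kappa: float = 2.0,
    pi: np.ndarray | None = None,
    seed: int = 0,
    ref_start: int = 1,
) -> tuple[CodonAlignment, np.ndarray]:
    """Evolve codon columns along the tree under a site-class mixture.

    Each site draws a mixture class; root codons come from π; branch
    transitions use the class- (and, for clade shifts, partition-)
    specific rate matrices.  Returns the alignment and true class labels.
    """
    rng = np.random.default_rng(seed)
    ta = TreeArrays.from_clade_tree(tree)
    if pi is None:
        pi = np.full(N_CODONS, 1.0 / N_CODONS)
    n_cat = max(int(ta.edge_category.max()), 0) + 1
    weights, om = _mixture_from_spec(model, n_cat)
    P = mixture_transition_matrices(ta, pi, kappa, weights, om, 1.0)
    C = len(weights)

    classes = rng.choice(C, size=n_sites, p=weights / weights.sum())
    states = np.empty((ta.n_nodes, n_sites), dtype=np.int64)
    states[ta.root] = rng.choice(N_CODONS, size=n_sites, p=pi)
    for node in ta.postorder[::-1]:
        if node == ta.root:
            continue
        par = states[ta.parent[node]]
        for c in range(C):
            idx = np.nonzero(classes == c)[0]
            if idx.size == 0:
                continue
            rows = P[c, node][par[idx]]  # (n_idx, 61)
            rows = rows / rows.sum(axis=1, keepdims=True)
            u = rng.random(idx.size)
            states[node, idx] = (rows.cumsum(axis=1) < u[:, None]).sum(axis=1)

    order = {t: i for i, t in enumerate(ta.leaf_names)}
    taxa = sorted(ta.leaf_names)
    codes = np.stack([states[order[t]] for t in taxa])
    aln = CodonAlignment(
        taxa=taxa,
        codes=codes,
        ref_map=np.arange(ref_start, ref_start + n_sites),
    )
    return aln, classes


def cmc_spec(
    p0: float, p1: float, omega0: float, omega_d: dict
) -> SiteClassModelSpec:
    """Clade Model C truth: omega_d maps 'background' and partition names."""
    return SiteClassModelSpec(
        "CmC",
        np.array([p0, p1, 1.0 - p0 - p1]),
        class_omegas=np.array([omega0, 1.0, np.nan]),
        divergent_omegas=dict(omega_d),
    )


def plant_covarying_pair(
    aln: CodonAlignment,
    pair: tuple[int, int],
    coupling: dict | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> CodonAlignment:
    """Rewrite column j as a residue-level function of column i.

    ``coupling`` maps one-letter amino acids to one-letter amino acids; by
    default the identity.  With ``noise`` = 0 the coupling must be a
    bijection on the residues present in column i, and the new column j
    carries exactly the entropy of column i (hence MI(i, j) = H(i)).
    With noise, each row keeps its original j residue with that
    probability.
    """
    rng = np.random.default_rng(seed)
    ci = aln.column_of_site(pair[0])
    cj = aln.column_of_site(pair[1])
    codes = aln.codes.copy()
    present = {
        CODON_AA[c] for c in codes[:, ci] if c >= 0
    }
    coupling = coupling or {a: a for a in present}
    if noise == 0.0:
        image = [coupling[a] for a in present]
        if len(set(image)) != len(image):
            raise ValueError("coupling must be a residue bijection in exact mode")
    for t in range(aln.n_taxa):
        src = codes[t, ci]
        if src < 0:
            continue
        if noise > 0 and rng.random() < noise:
            continue
        target_aa = coupling[CODON_AA[src]]
        codes[t, cj] = CODON_INDEX[AA_TO_CODON[target_aa]]
    return CodonAlignment(
        taxa=list(aln.taxa), codes=codes, ref_map=aln.ref_map.copy()
    )


def simulate_binary_traits(
    tree: CladeTree,
    rates,
    model: str = "independent",
    seed: int = 0,
    sites: tuple[int, int] = (0, 1),
    root: str = "stationary",
) -> tuple[BinaryTraitVector, BinaryTraitVector]:
    """One correlated-or-not binary trait pair evolved on the tree."""
    rates = np.asarray(rates, dtype=float)
    if np.any(rates < 0):
        raise ValueError("rates must be nonnegative")
    r8 = expand_independent_rates(rates) if model == "independent" else rates
    ta = TreeArrays.from_clade_tree(tree)
    rng = np.random.default_rng(seed)
    if np.all(r8 == 0):
        # zero rates: every leaf inherits the root state
        pi = np.full(4, 0.25)
        s = rng.choice(4, p=pi)
        x = np.full(ta.n_leaves, s >> 1)
        y = np.full(ta.n_leaves, s & 1)
    else:
        x, y = simulate_joint_traits(
            ta, r8, 1, rng, root_equal=(root == "equal")
        )
        x, y = x[0], y[0]
    tx = BinaryTraitVector(
        site=sites[0], consensus="?", taxa=list(ta.leaf_names),
        values=[int(v) for v in x],
    )
    ty = BinaryTraitVector(
        site=sites[1], consensus="?", taxa=list(ta.leaf_names),
        values=[int(v) for v in y],
    )
    return tx, ty


def simulate_release_trace(
    y0: float, a: float, b: float, noise_sd: float,
    t_end: float = 30.0, dt: float = 0.5, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Exponential-rise fluorescence trace sampled every ``dt`` minutes."""
    if b <= 0:
        raise ValueError("rate constant must be positive")
    rng = np.random.default_rng(seed)
    t = np.arange(0.0, t_end + dt / 2, dt)
    y = y0 + a * (1.0 - np.exp(-b * t))
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=t.size)
    return t, y


def simulate_spectrum(
    lambda_max: float, scale: float = 1.0, noise_sd: float = 0.0,
    grid: np.ndarray | None = None, seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """A1-template absorbance spectrum with i.i.d. Gaussian noise.

    ``noise_sd`` is absolute (same units as the scaled template, whose
    peak is ~``scale``).
    """
    rng = np.random.default_rng(seed)
    lam = (
        np.asarray(grid, dtype=float)
        if grid is not None
        else np.arange(400.0, 650.0 + 0.5, 1.0)
    )
    y = scale * a1_template(lam, lambda_max)
    if noise_sd > 0:
        y = y + rng.normal(scale=noise_sd, size=lam.size)
    return lam, y


# ------------------------------------------------------------- full bench
def simulate_benchmark(spec: SimSpec, outdir: str | Path) -> dict:
    """Write a complete synthetic study (FASTA/Newick/YAML + truth JSON)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree = two_clade_tree(spec.n_taxa, height=spec.tree_height)
    if spec.clade_shift:
        # foreground = named partitions only; the rest is background
        tree.partitions = [
            p for p in tree.partitions if p.name in spec.clade_shift
        ]
    model = spec.model
    if model is None:
        if spec.clade_shift:
            div = {"background": 0.24}
            for p in tree.partitions:
                div[p.name] = spec.clade_shift[p.name]
            model = cmc_spec(0.65, 0.05, 0.02, div)
        else:
            model = default_m0_spec(0.2)
    aln, classes = simulate_codon_alignment(
        tree, model, spec.n_sites, kappa=spec.kappa, seed=spec.seed
    )
    for k, pair in enumerate(spec.planted_pairs):
        site_i, site_j = pair[0], pair[1]
        coupling = pair[2] if len(pair) > 2 else None
        noise = pair[3] if len(pair) > 3 else 0.0
        aln = plant_covarying_pair(
            aln, (site_i, site_j), coupling, noise, seed=spec.seed + 1000 + k
        )
    write_codon_alignment(aln, outdir / "alignment.fasta")
    (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
    parts = {
        "partitions": [
            {"name": p.name, "taxa": list(p.taxa), "kind": p.kind}
            for p in tree.partitions
        ]
    }
    (outdir / "partitions.yaml").write_text(yaml.safe_dump(parts))
    truth = {
        "seed": spec.seed,
        "model_id": model.model_id,
        "kappa": spec.kappa,
        "n_sites": spec.n_sites,
        "site_classes": [int(c) for c in classes],
        "planted_pairs": [list(p[:2]) for p in spec.planted_pairs],
        "clade_shift": spec.clade_shift,
    }
    (outdir / "truth.yaml").write_text(yaml.safe_dump(truth))
    return {
        "alignment": outdir / "alignment.fasta",
        "tree": outdir / "tree.nwk",
        "partitions": outdir / "partitions.yaml",
        "truth": outdir / "truth.yaml",
    }
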
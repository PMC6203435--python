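"""Codon-based marginal ancestral reconstruction under a fitted site model.

For each internal node and site the marginal posterior over the 61 sense
codons combines the below-node partial likelihoods with the likelihood of
the rest of the tree (outside pass), per mixture class, and then mixes
classes by their per-site empirical-Bayes posterior from the fit.  The MAP
codon is the reconstruction; ties are broken by codon lexicographic order
and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genetic_code import CODON_AA, N_CODONS, SENSE_CODONS
from .io_core import GAP, CodonAlignment
from .codon_models import LikelihoodEngine, SiteClassFit
from .trees import CladeTree


@dataclass
class AncestralPosterior:
    node: int
    site: int
    posterior: np.ndarray  # (61,)
    map_codon: str
    map_aa: str
    map_prob: float
    tie: bool = False


def _class_posteriors_at_nodes(engine: LikelihoodEngine, cols: np.ndarray,
                               codes: np.ndarray, P: np.ndarray):
    """Inside/outside pass for one mixture class.

    codes: (n_leaves, n_cols) codon indices in engine leaf order.
    Returns (post[node] -> (n_cols, 61) normalized, site_loglik (n_cols,)).
    """
    ta = engine.tree_arrays
    ns = codes.shape[1]
    inside: list = [None] * ta.n_nodes
    logscale = np.zeros(ns)
    for i in range(ta.n_leaves):
        L = np.zeros((ns, N_CODONS))
        gap = codes[i] == GAP
        L[gap, :] = 1.0
        ok = ~gap
        L[ok, codes[i][ok]] = 1.0
        inside[i] = L
    for node in ta.postorder:
        kids = ta.children[node]
        if not kids:
            continue
        acc = np.ones((ns, N_CODONS))
        for ch in kids:
            acc *= inside[ch] @ P[ch].T
        m = np.clip(acc.max(axis=1), 1e-300, None)
        acc /= m[:, None]
        logscale += np.log(m)
        inside[node] = acc
    root = ta.root
    site_lik = inside[root] @ engine.pi
    site_loglik = np.log(np.clip(site_lik, 1e-300, None)) + logscale

    # outside pass (scale-free: posteriors are normalized per node)
    outside: list = [None] * ta.n_nodes
    outside[root] = np.broadcast_to(engine.pi, (ns, N_CODONS)).copy()
    for node in ta.postorder[::-1]:
        kids = ta.children[node]
        if not kids:
            continue
        msgs = {ch: inside[ch] @ P[ch].T for ch in kids}
        for ch in kids:
            prod = outside[node].copy()
            for other in kids:
                if other != ch:
                    prod *= msgs[other]
            F = prod @ P[ch]
            m = np.clip(F.max(axis=1), 1e-300, None)
            outside[ch] = F / m[:, None]
    posts = {}
    for node in range(ta.n_leaves, ta.n_nodes):
        raw = inside[node] * outside[node]
        z = raw.sum(axis=1, keepdims=True)
        posts[node] = raw / np.clip(z, 1e-300, None)
    return posts, site_loglik


def marginal_reconstruct(
    aln: CodonAlignment,
    tree: CladeTree,
    fit: SiteClassFit,
    nodes=None,
    sites=None,
    engine: LikelihoodEngine | None = None,
) -> list[AncestralPosterior]:
    """Marginal ancestral codon posteriors at internal nodes.

    ``nodes``: internal node ids (TreeArrays numbering) or None for all;
    ``sites``: reference residue numbers or None for all columns.
    """
    engine = engine or LikelihoodEngine(aln, tree, pi=fit.pi)
    ta = engine.tree_arrays
    if sites is None:
        cols = np.arange(aln.n_sites)
        site_numbers = aln.ref_map
    else:
        cols = np.array([aln.column_of_site(s) for s in sites], dtype=np.intp)
        site_numbers = np.asarray(list(sites))
    if nodes is None:
        nodes = list(range(ta.n_leaves, ta.n_nodes))
    for node in nodes:
        if node < ta.n_leaves or node >= ta.n_nodes:
            raise ValueError(f"node {node} is not an internal node")

    order = {t: i for i, t in enumerate(aln.taxa)}
    rows = [order[t] for t in ta.leaf_names]
    codes = aln.codes[np.ix_(rows, cols)]

    C = len(fit.class_weights)
    Pall = engine.class_transition_matrices(
        fit.kappa, fit.class_weights, fit.class_omegas, fit.scale
    )
    class_site_post = fit.site_posteriors[cols]  # (n_cols, C)
    mixed = {node: np.zeros((len(cols), N_CODONS)) for node in nodes}
    for c in range(C):
        posts, _ = _class_posteriors_at_nodes(engine, cols, codes, Pall[c])
        for node in nodes:
            mixed[node] += class_site_post[:, c][:, None] * posts[node]

    out = []
    for node in nodes:
        for k, site in enumerate(site_numbers):
            p = mixed[node][k]
            p = p / p.sum()
            best = int(np.argmax(p))  # argmax returns first (lexicographic) tie
            tie = bool(np.sum(np.isclose(p, p[best], atol=1e-6)) > 1)
            out.append(
                AncestralPosterior(
                    node=node,
                    site=int(site),
                    posterior=p,
                    map_codon=SENSE_CODONS[best],
                    map_aa=CODON_AA[best],
                    map_prob=float(p[best]),
                    tie=tie,
                )
            )
    return out


def node_for_mrca(tree: CladeTree, taxa, engine: LikelihoodEngine) -> int:
    """TreeArrays id of the MRCA of the given taxon labels."""
    ta = engine.tree_arrays
    leaf_ids = {ta.leaf_names.index(t) for t in taxa}
    # climb from one leaf until the subtree covers all requested leaves
    below = {i: {i} for i in range(ta.n_leaves)}
    for node in ta.postorder:
        if ta.children[node]:
            s = set()
            for ch in ta.children[node]:
                s |= below[ch]
            below[node] = s
    for node in ta.postorder:
        if node >= ta.n_leaves and leaf_ids <= below[node]:
            return node
    raise ValueError("MRCA not found")


def motif_report(
    posteriors: list[AncestralPosterior],
    sites=(119, 122, 123, 124),
) -> pd.DataFrame:
    """Per-node amino-acid motif over the given sites with min codon posterior."""
    rows = {}
    for ap in posteriors:
        rows.setdefault(ap.node, {})[ap.site] = ap
    out = []
    for node, by_site in sorted(rows.items()):
        missing = [s for s in sites if s not in by_site]
        if missing:
            raise ValueError(f"node {node}: missing sites {missing}")
        motif = "".join(by_site[s].map_aa for s in sites)
        minp = min(by_site[s].map_prob for s in sites)
        tie = any(by_site[s].tie for s in sites)
        out.append(
            {"node": node, "motif": motif, "min_posterior": minp, "tie": tie}
        )
    return pd.DataFrame(out)


def reconstruction_table(posteriors: list[AncestralPosterior]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "node": ap.node,
                "site": ap.site,
                "map_codon": ap.map_codon,
                "map_aa": ap.map_aa,
                "posterior": ap.map_prob,
                "tie": ap.tie,
            }
            for ap in posteriors
        ]
    )
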
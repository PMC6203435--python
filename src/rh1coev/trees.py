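"""Phylogeny container: Newick I/O, named foreground partitions, pruning.

A :class:`CladeTree` wraps a rooted dendropy tree whose leaves are the
alignment taxa, carries branch lengths in expected substitutions per codon,
and names foreground partitions either as whole clades (all branches of the
MRCA subtree, stem included) or as single ancestral branches (the stem edge
only).  For likelihood work the tree is flattened once into postorder index
arrays (:class:`TreeArrays`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import dendropy
import numpy as np
import yaml


@dataclass
class PartitionSpec:
    """A named foreground: a clade (MRCA subtree incl. stem) or one branch."""

    name: str
    taxa: tuple[str, ...]
    kind: str = "clade"  # "clade" | "branch"

    def __post_init__(self):
        if self.kind not in ("clade", "branch"):
            raise ValueError(f"unknown partition kind {self.kind!r}")
        if not self.taxa:
            raise ValueError("partition needs at least one taxon")


@dataclass
class CladeTree:
    tree: dendropy.Tree
    partitions: list[PartitionSpec] = field(default_factory=list)

    # ------------------------------------------------------------------ io
    @classmethod
    def from_newick(cls, source: str | Path, partitions=None) -> "CladeTree":
        text = Path(source).read_text() if isinstance(source, Path) else str(source)
        if "(" not in text and Path(str(source)).exists():
            text = Path(str(source)).read_text()
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        tree.is_rooted = True
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise ValueError("Newick tree must carry branch lengths")
            if edge.length is not None and edge.length < 0:
                raise ValueError("negative branch length")
        return cls(tree=tree, partitions=list(partitions or []))

    def to_newick(self) -> str:
        return self.tree.as_string(
            schema="newick", unquoted_underscores=True, suppress_rooting=True
        ).strip()

    @property
    def taxa(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    def copy(self) -> "CladeTree":
        return CladeTree(
            tree=self.tree.clone(depth=1), partitions=list(self.partitions)
        )

    # ------------------------------------------------------- partitions
    @classmethod
    def load_partitions_yaml(cls, path: str | Path) -> list[PartitionSpec]:
        """Sidecar YAML: {partitions: [{name, taxa: [...], kind}]}"""
        doc = yaml.safe_load(Path(path).read_text())
        specs = []
        for entry in doc.get("partitions", []):
            specs.append(
                PartitionSpec(
                    name=entry["name"],
                    taxa=tuple(entry["taxa"]),
                    kind=entry.get("kind", "clade"),
                )
            )
        return specs

    def edge_categories(self) -> dict:
        """Map dendropy edge -> partition index (0 = background).

        Partition i (1-based) claims the MRCA subtree edges ("clade") or the
        stem edge only ("branch").  Overlapping partitions are an error.
        """
        cat = {}
        labels = set(self.taxa)
        for idx, part in enumerate(self.partitions, start=1):
            unknown = set(part.taxa) - labels
            if unknown:
                raise ValueError(f"partition {part.name!r}: unknown taxa {sorted(unknown)}")
            mrca = self.tree.mrca(taxon_labels=list(part.taxa))
            if part.kind == "branch":
                edges = [mrca.edge]
            else:
                edges = [mrca.edge] + [
                    n.edge for n in mrca.preorder_iter() if n is not mrca
                ]
            for e in edges:
                if e.head_node is self.tree.seed_node:
                    continue
                if e in cat:
                    raise ValueError(
                        f"partitions overlap at edge above {e.head_node}"
                    )
                cat[e] = idx
        return cat

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)

    # ---------------------------------------------------------- queries
    def patristic_matrix(self) -> tuple[list[str], np.ndarray]:
        pdm = self.tree.phylogenetic_distance_matrix()
        labels = sorted(self.taxa)
        taxon = {t.label: t for t in self.tree.taxon_namespace}
        n = len(labels)
        out = np.zeros((n, n))
        for i, a in enumerate(labels):
            for j, b in enumerate(labels):
                if i < j:
                    d = pdm.patristic_distance(taxon[a], taxon[b])
                    out[i, j] = out[j, i] = d
        return labels, out

    def total_height(self) -> float:
        return max(
            leaf.distance_from_root() for leaf in self.tree.leaf_node_iter()
        )

    # ------------------------------------------------------------ prune
    def pruned_to(self, keep: set[str]) -> "CladeTree":
        keep = set(keep)
        labels = set(self.taxa)
        unknown = keep - labels
        if unknown:
            raise ValueError(f"unknown taxa: {sorted(unknown)}")
        if len(keep) < 2:
            raise ValueError("pruning must keep at least 2 taxa")
        new = self.tree.clone(depth=1)
        new.retain_taxa_with_labels(list(keep))
        # dendropy suppresses degree-2 nodes, summing branch lengths
        parts = [
            PartitionSpec(p.name, tuple(t for t in p.taxa if t in keep), p.kind)
            for p in self.partitions
        ]
        parts = [p for p in parts if p.taxa]
        return CladeTree(tree=new, partitions=parts)


# ----------------------------------------------------------- flat arrays
@dataclass
class TreeArrays:
    """Index-array view of a rooted tree for vectorized pruning.

    Nodes are numbered so that leaves come first (in ``leaf_names`` order);
    ``postorder`` visits children before parents and ends at the root.
    ``edge_length[i]`` is the branch above node i (0.0 for the root) and
    ``edge_category[i]`` its foreground partition index (0 = background).
    """

    n_nodes: int
    n_leaves: int
    leaf_names: list[str]
    parent: np.ndarray
    children: list[list[int]]
    postorder: np.ndarray
    edge_length: np.ndarray
    edge_category: np.ndarray
    root: int

    @classmethod
    def from_clade_tree(cls, ct: CladeTree) -> "TreeArrays":
        cat_map = ct.edge_categories() if ct.partitions else {}
        leaves = [n for n in ct.tree.leaf_node_iter()]
        leaf_names = [n.taxon.label for n in leaves]
        internal = [n for n in ct.tree.postorder_node_iter() if not n.is_leaf()]
        index = {}
        for i, n in enumerate(leaves):
            index[id(n)] = i
        for k, n in enumerate(internal):
            index[id(n)] = len(leaves) + k
        n_nodes = len(leaves) + len(internal)
        parent = np.full(n_nodes, -1, dtype=np.intp)
        edge_length = np.zeros(n_nodes)
        edge_category = np.zeros(n_nodes, dtype=np.intp)
        children: list[list[int]] = [[] for _ in range(n_nodes)]
        for n in ct.tree.postorder_node_iter():
            i = index[id(n)]
            if n.parent_node is not None:
                parent[i] = index[id(n.parent_node)]
                children[parent[i]].append(i)
                edge_length[i] = n.edge.length or 0.0
                edge_category[i] = cat_map.get(n.edge, 0)
        postorder = np.array(
            [index[id(n)] for n in ct.tree.postorder_node_iter()], dtype=np.intp
        )
        root = index[id(ct.tree.seed_node)]
        return cls(
            n_nodes=n_nodes,
            n_leaves=len(leaves),
            leaf_names=leaf_names,
            parent=parent,
            children=children,
            postorder=postorder,
            edge_length=edge_length,
            edge_category=edge_category,
            root=root,
        )

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    def scaled(self, factor: float) -> "TreeArrays":
        out = TreeArrays(
            n_nodes=self.n_nodes,
            n_leaves=self.n_leaves,
            leaf_names=self.leaf_names,
            parent=self.parent,
            children=self.children,
            postorder=self.postorder,
            edge_length=self.edge_length * factor,
            edge_category=self.edge_category,
            root=self.root,
        )
        return out


def balanced_tree(n_taxa: int, height: float = 1.0, prefix: str = "t") -> CladeTree:
    """Ultrametric balanced(-ish) tree over ``n_taxa`` leaves of given height.

    The taxon set is split recursively into halves; every root-to-tip path
    has total length ``height``.  Deterministic; used as the benchmark tree.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    names = [f"{prefix}{i + 1}" for i in range(n_taxa)]

    def build(labels: list[str], h: float) -> str:
        """Subtree spanning exactly ``h`` from stem top to every tip."""
        if len(labels) == 1:
            return f"{labels[0]}:{h:.10g}"
        levels = int(np.ceil(np.log2(len(labels)))) + 1  # stem + splits below
        stem = h / levels
        half = len(labels) // 2
        left = build(labels[:half], h - stem)
        right = build(labels[half:], h - stem)
        return f"({left},{right}):{stem:.10g}"

    half = n_taxa // 2
    core = f"({build(names[:half], height)},{build(names[half:], height)});"
    return CladeTree.from_newick(core)


def star_tree(n_taxa: int, height: float = 1.0, prefix: str = "t") -> CladeTree:
    """Star phylogeny: every leaf hangs off the root at ``height``.

    Useful as a no-shared-branch control: columns evolved on it are
    independent across taxa given the root, so any inter-column
    covariation must be planted.
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    newick = (
        "(" + ",".join(f"{prefix}{i + 1}:{height:.10g}" for i in range(n_taxa))
        + ");"
    )
    return CladeTree.from_newick(newick)


def two_clade_tree(
    n_taxa: int = 30,
    height: float = 1.0,
    names: tuple[str, str] = ("cladeA", "cladeB"),
) -> CladeTree:
    """Benchmark tree: balanced, unit height, split into two named clades.

    Mimics a teleost/tetrapod-style partition structure at desk scale: the
    first half of the taxa form partition ``names[0]``, the rest ``names[1]``.
    """
    ct = balanced_tree(n_taxa, height=height)
    taxa = ct.taxa
    half = n_taxa // 2
    ct.partitions = [
        PartitionSpec(names[0], tuple(taxa[:half]), "clade"),
        PartitionSpec(names[1], tuple(taxa[half:]), "clade"),
    ]
    return ct
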
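"""Phylogenetic trees as flat arrays for fast likelihood traversal.

Newick parsing is delegated to dendropy; internally the tree is stored as a
postorder-indexed array structure (each non-root node owns the edge to its
parent).  The substitution models are time-reversible, so the likelihood
does not depend on where the (arbitrary) root is placed; unrooted input is
used as-is with its basal multifurcation serving as the root.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import dendropy
import numpy as np

DEFAULT_BRANCH_LENGTH = 0.1


class TaxonMismatchError(ValueError):
    """Tree and alignment taxa do not match; message names the offenders."""


@dataclass
class PhyloTree:
    """Array-backed rooted view of a (possibly unrooted) phylogeny.

    Nodes are indexed in postorder with the root last.  ``parent[i]`` is the
    parent index (-1 for the root), ``edge_length[i]`` the length of the
    edge above node i (in expected substitutions per site), ``leaf_taxon[i]``
    the taxon name for leaves and None for internal nodes.
    """

    parent: np.ndarray
    edge_length: np.ndarray
    leaf_taxon: list
    children: list = field(init=False)

    def __post_init__(self) -> None:
        n = len(self.parent)
        ch: list[list[int]] = [[] for _ in range(n)]
        for i, p in enumerate(self.parent):
            if p >= 0:
                ch[p].append(i)
        self.children = ch
        self.edge_length = np.asarray(self.edge_length, dtype=float)

    # -- basic structure ----------------------------------------------------

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def leaves(self) -> list[int]:
        return [i for i in range(self.n_nodes) if not self.children[i]]

    @property
    def taxa(self) -> list[str]:
        return [self.leaf_taxon[i] for i in self.leaves]

    @property
    def n_edges(self) -> int:
        return self.n_nodes - 1

    @property
    def total_length(self) -> float:
        return float(self.edge_length[: self.root].sum())

    def with_lengths(self, lengths: np.ndarray) -> "PhyloTree":
        el = np.asarray(lengths, dtype=float)
        full = np.append(el, 0.0) if len(el) == self.n_edges else el.copy()
        return PhyloTree(
            parent=self.parent.copy(),
            edge_length=full,
            leaf_taxon=list(self.leaf_taxon),
        )

    def branch_lengths(self) -> np.ndarray:
        """Lengths of the n_nodes - 1 real edges (root excluded)."""
        return self.edge_length[: self.root].copy()

    # -- construction -------------------------------------------------------

    @classmethod
    def from_dendropy(cls, tree: dendropy.Tree,
                      default_length: float = DEFAULT_BRANCH_LENGTH) -> "PhyloTree":
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        parent = np.full(len(nodes), -1, dtype=np.int64)
        lengths = np.zeros(len(nodes))
        taxa: list = [None] * len(nodes)
        for nd in nodes:
            i = index[id(nd)]
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                el = nd.edge.length
                lengths[i] = default_length if el is None else max(float(el), 0.0)
            if nd.is_leaf():
                if nd.taxon is None:
                    raise ValueError("leaf without taxon label")
                taxa[i] = nd.taxon.label.replace(" ", "_")
        return cls(parent=parent, edge_length=lengths, leaf_taxon=taxa)

    @classmethod
    def from_newick(cls, newick: str,
                    default_length: float = DEFAULT_BRANCH_LENGTH) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=newick, schema="newick", preserve_underscores=True
        )
        # suppress dendropy's implicit bifurcating root over unrooted trees
        if len(tree.seed_node.child_nodes()) == 2 and len(tree.leaf_nodes()) > 2:
            tree.collapse_basal_bifurcation()
        return cls.from_dendropy(tree, default_length=default_length)

    def to_newick(self) -> str:
        def render(i: int) -> str:
            if not self.children[i]:
                label = self.leaf_taxon[i]
            else:
                label = f"({','.join(render(c) for c in self.children[i])})"
            if i == self.root:
                return label + ";"
            return f"{label}:{self.edge_length[i]:.10g}"

        return render(self.root)

    # -- validation ---------------------------------------------------------

    def match_taxa(self, aln_taxa: list[str]) -> dict[int, int]:
        """Map leaf node index -> alignment row; raise listing mismatches."""
        aln_index = {t: i for i, t in enumerate(aln_taxa)}
        tree_taxa = set(self.taxa)
        extra = sorted(tree_taxa - set(aln_taxa))
        missing = sorted(set(aln_taxa) - tree_taxa)
        if extra or missing:
            raise TaxonMismatchError(
                f"tree/alignment taxon mismatch; only in tree: {extra}; "
                f"only in alignment: {missing}"
            )
        return {i: aln_index[self.leaf_taxon[i]] for i in self.leaves}


def read_tree(path: str | os.PathLike,
              default_length: float = DEFAULT_BRANCH_LENGTH) -> PhyloTree:
    """Read a Newick tree file."""
    with open(path) as fh:
        return PhyloTree.from_newick(fh.read(), default_length=default_length)


def random_tree(
    n_taxa: int,
    rng: np.random.Generator,
    total_length: float | None = None,
    taxon_prefix: str = "t",
) -> PhyloTree:
    """Random binary topology by sequential pair joining, exponential edge
    lengths, optionally rescaled to a target total tree length."""
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    parent: list[int] = []
    lengths: list[float] = []
    taxa: list = []

    nodes = []
    for i in range(n_taxa):
        parent.append(-1)
        lengths.append(float(rng.exponential(0.1)))
        taxa.append(f"{taxon_prefix}{i + 1}")
        nodes.append(i)
    active = list(nodes)
    while len(active) > 2:
        a, b = sorted(rng.choice(len(active), size=2, replace=False))
        na, nb = active[a], active[b]
        new = len(parent)
        parent.append(-1)
        lengths.append(float(rng.exponential(0.1)))
        taxa.append(None)
        parent[na] = new
        parent[nb] = new
        active = [x for x in active if x not in (na, nb)] + [new]
    root = len(parent)
    parent.append(-1)
    lengths.append(0.0)
    taxa.append(None)
    for x in active:
        parent[x] = root

    # reindex to postorder
    children: list[list[int]] = [[] for _ in parent]
    for i, p in enumerate(parent):
        if p >= 0:
            children[p].append(i)
    order: list[int] = []

    def post(i: int) -> None:
        for c in children[i]:
            post(c)
        order.append(i)

    post(root)
    remap = {old: new for new, old in enumerate(order)}
    n = len(order)
    new_parent = np.full(n, -1, dtype=np.int64)
    new_lengths = np.zeros(n)
    new_taxa: list = [None] * n
    for old, newi in remap.items():
        new_parent[newi] = remap[parent[old]] if parent[old] >= 0 else -1
        new_lengths[newi] = lengths[old]
        new_taxa[newi] = taxa[old]
    tree = PhyloTree(parent=new_parent, edge_length=new_lengths, leaf_taxon=new_taxa)
    if total_length is not None:
        cur = tree.total_length
        tree.edge_length *= total_length / cur
    return tree
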
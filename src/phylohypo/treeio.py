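"""Reading, writing and interrogating phylogenetic trees and MCMC tree samples.

Trees are thin wrappers around :class:`dendropy.Tree`, which handles the
Newick/NEXUS dialects produced by the usual Bayesian and maximum-likelihood
tools (quoted labels, ``[&...]`` metadata comments, translate tables,
scientific-notation branch lengths). The wrapper adds the split/bipartition
bookkeeping the hypothesis tests downstream are built on.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "Bipartition",
    "PhyloTree",
    "TreeSample",
    "NewickParseError",
    "parse_newick",
    "parse_nexus_trees",
    "read_tree_file",
    "write_newick",
    "write_nexus",
    "bipartitions",
    "patristic_matrix",
    "apply_burnin",
]


class NewickParseError(ValueError):
    """Raised when a Newick/NEXUS input cannot be parsed."""


@dataclass(frozen=True)
class Bipartition:
    """A two-way split of the taxon set induced by removing one tree edge.

    The canonical stored ``side_a`` is the side containing the
    lexicographically smallest taxon label, which makes equality and hashing
    well defined regardless of which subtree the split was read off.
    """

    side_a: frozenset
    side_b: frozenset

    @classmethod
    def from_split(cls, side, all_taxa):
        side = frozenset(side)
        all_taxa = frozenset(all_taxa)
        if not side or side == all_taxa:
            raise ValueError("a bipartition needs two non-empty sides")
        if not side <= all_taxa:
            raise ValueError("split side is not a subset of the taxon set")
        other = all_taxa - side
        if min(side) > min(other):
            side, other = other, side
        return cls(side_a=side, side_b=other)

    @property
    def taxa(self):
        return self.side_a | self.side_b

    def __str__(self):
        return "{%s} | {%s}" % (
            ",".join(sorted(self.side_a)),
            ",".join(sorted(self.side_b)),
        )


class PhyloTree:
    """A rooted or unrooted tree with branch lengths over a taxon namespace.

    Wraps a :class:`dendropy.Tree`. A tree is considered rooted iff its root
    node has exactly two children, unless ``rooted`` is forced at
    construction (BEAST samples are rooted by convention even if a basal
    trifurcation appears after manipulation).
    """

    def __init__(self, dtree: dendropy.Tree, rooted: bool | None = None):
        self._dtree = dtree
        self._rooted_override = rooted

    # -- basic structure ---------------------------------------------------

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._dtree

    @property
    def root(self):
        return self._dtree.seed_node

    @property
    def rooted(self) -> bool:
        if self._rooted_override is not None:
            return self._rooted_override
        return len(self.root.child_nodes()) == 2

    @property
    def taxa(self) -> frozenset:
        return frozenset(
            leaf.taxon.label for leaf in self._dtree.leaf_node_iter()
        )

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._dtree.leaf_node_iter())

    def copy(self) -> "PhyloTree":
        return PhyloTree(self._dtree.clone(depth=1), rooted=self._rooted_override)

    def leaf_sets(self):
        """Map every node to the frozenset of leaf labels below it (post-order)."""
        sets = {}
        for node in self._dtree.postorder_node_iter():
            if node.is_leaf():
                sets[node] = frozenset([node.taxon.label])
            else:
                s = frozenset()
                for child in node.child_nodes():
                    s = s | sets[child]
                sets[node] = s
        return sets

    def clades(self, include_trivial: bool = False):
        """Frozensets of leaf labels of all internal nodes (root excluded)."""
        sets = self.leaf_sets()
        all_taxa = sets[self.root]
        out = set()
        for node, s in sets.items():
            if node is self.root:
                continue
            if not include_trivial and len(s) < 2:
                continue
            if s != all_taxa:
                out.add(s)
        return out

    # -- representations ---------------------------------------------------

    def newick(self, include_lengths: bool = True) -> str:
        kwargs = dict(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            preserve_spaces=True,  # labels with spaces are emitted quoted
        )
        if not include_lengths:
            kwargs["suppress_edge_lengths"] = True
        return self._dtree.as_string(**kwargs).strip()

    def __repr__(self):
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_leaves} leaves>"


@dataclass
class TreeSample:
    """An ordered collection of trees from one MCMC run.

    All trees must share one taxon namespace; a mismatch is an error because
    every downstream count (model odds, root frequencies, clade credibility)
    assumes a single namespace.
    """

    trees: list
    burnin_fraction: float = 0.0
    source: str = ""

    def __post_init__(self):
        if self.trees:
            taxa0 = self.trees[0].taxa
            for i, t in enumerate(self.trees):
                if t.taxa != taxa0:
                    raise ValueError(
                        f"tree {i} has a different taxon set from tree 0 "
                        f"in sample {self.source!r}"
                    )

    def __len__(self):
        return len(self.trees)

    def __iter__(self):
        return iter(self.trees)

    @property
    def taxa(self) -> frozenset:
        if not self.trees:
            return frozenset()
        return self.trees[0].taxa


# ---------------------------------------------------------------------------
# parsing / writing


def parse_newick(text: str, rooted: bool | None = None) -> PhyloTree:
    """Parse a single Newick string into a :class:`PhyloTree`.

    Quoted labels are unquoted, ``[...]`` comments stripped and underscores
    kept verbatim (no underscore-to-space conversion).
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return PhyloTree(dtree, rooted=rooted)


def parse_nexus_trees(
    text: str, burnin_fraction: float = 0.0, rooted: bool | None = None,
    source: str = "",
) -> TreeSample:
    """Parse the TREES block of a NEXUS file (BEAST/MrBayes dialects).

    Translate-table indices are resolved to labels, ``[&...]`` metadata
    comments dropped, tree order preserved.
    """
    try:
        tlist = dendropy.TreeList.get(
            data=text,
            schema="nexus",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:
        raise NewickParseError(f"cannot parse NEXUS trees: {exc}") from exc
    if len(tlist) == 0:
        raise NewickParseError("NEXUS input contains no trees")
    return TreeSample(
        trees=[PhyloTree(t, rooted=rooted) for t in tlist],
        burnin_fraction=burnin_fraction,
        source=source,
    )


def parse_newick_list(text: str, rooted: bool | None = None, source: str = "") -> TreeSample:
    """Parse a plain list of Newick strings (one tree per line)."""
    trees = []
    for line in text.splitlines():
        line = line.strip()
        if line:
            trees.append(parse_newick(line, rooted=rooted))
    if not trees:
        raise NewickParseError("no trees found in input")
    return TreeSample(trees=trees, source=source)


def read_tree_file(path, rooted: bool | None = None) -> TreeSample:
    """Read a tree sample from a file, sniffing NEXUS vs plain Newick."""
    with open(path) as fh:
        text = fh.read()
    if text.lstrip()[:6].upper() == "#NEXUS":
        return parse_nexus_trees(text, rooted=rooted, source=str(path))
    return parse_newick_list(text, rooted=rooted, source=str(path))


def write_newick(tree: PhyloTree) -> str:
    """Serialize a tree to Newick; labels with spaces are emitted quoted."""
    return tree.newick()


def _nexus_safe(label: str) -> str:
    if any(c in label for c in " ()[]{}/\\,;:=*'\"`+<>-"):
        return "'" + label.replace("'", "''") + "'"
    return label


def _render_newick(tree: PhyloTree, label_fn) -> str:
    def rec(node):
        if node.is_leaf():
            s = label_fn(node.taxon.label)
        else:
            s = "(" + ",".join(rec(c) for c in node.child_nodes()) + ")"
        if node.parent_node is not None and node.edge.length is not None:
            s += f":{node.edge.length!r}"
        return s

    return rec(tree.root) + ";"


def write_nexus(sample: TreeSample) -> str:
    """Serialize a tree sample as a NEXUS TREES block with a translate table."""
    if not sample.trees:
        raise ValueError("empty tree sample")
    labels = sorted(sample.taxa)
    index = {lab: str(i + 1) for i, lab in enumerate(labels)}
    out = io.StringIO()
    out.write("#NEXUS\n\nBegin trees;\n\tTranslate\n")
    for i, lab in enumerate(labels):
        sep = ",\n" if i < len(labels) - 1 else "\n"
        out.write(f"\t\t{i + 1} {_nexus_safe(lab)}{sep}")
    out.write("\t\t;\n")
    for i, tree in enumerate(sample.trees):
        newick = _render_newick(tree, lambda lab: index[lab])
        rooting = "[&R] " if tree.rooted else ""
        out.write(f"tree STATE_{i} = {rooting}{newick}\n")
    out.write("End;\n")
    return out.getvalue()


# ---------------------------------------------------------------------------
# interrogation


def bipartitions(tree: PhyloTree) -> set:
    """All non-trivial splits induced by internal edges.

    For a fully resolved unrooted tree on *n* taxa this has exactly ``n - 3``
    elements; a rooted binary tree's two root edges induce the same split and
    are counted once.
    """
    sets = tree.leaf_sets()
    all_taxa = sets[tree.root]
    out = set()
    for node, s in sets.items():
        if node is tree.root:
            continue
        if len(s) < 2 or len(all_taxa - s) < 2:
            continue
        out.add(Bipartition.from_split(s, all_taxa))
    return out


def patristic_matrix(tree: PhyloTree) -> pd.DataFrame:
    """Symmetric matrix of path-length (patristic) distances between leaves."""
    for edge in tree.dendropy_tree.preorder_edge_iter():
        if edge.head_node is tree.root:
            continue
        if edge.length is None:
            head = edge.head_node
            name = head.taxon.label if head.is_leaf() else "an internal node"
            raise ValueError(f"missing branch length on the edge above {name}")
    pdm = tree.dendropy_tree.phylogenetic_distance_matrix()
    labels = sorted(tree.taxa)
    taxa = {t.label: t for t in tree.dendropy_tree.taxon_namespace}
    n = len(labels)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
            mat[i, j] = mat[j, i] = d
    return pd.DataFrame(mat, index=labels, columns=labels)


def apply_burnin(sample: TreeSample, fraction: float) -> TreeSample:
    """Discard the leading ``floor(fraction * N)`` trees of a sample."""
    if not (0 <= fraction < 1):
        raise ValueError(f"burn-in fraction must be in [0, 1), got {fraction}")
    n_drop = math.floor(fraction * len(sample.trees))
    return TreeSample(
        trees=sample.trees[n_drop:],
        burnin_fraction=0.0,
        source=sample.source,
    )
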
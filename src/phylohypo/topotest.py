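"""Topology hypothesis predicates and posterior summaries of tree samples.

The Bayesian test implemented here is the posterior-model-odds device: a
topological hypothesis M0 (for instance, "adenoviruses and NCLDVs are sister
groups") is scored by counting how many trees in a posterior MCMC sample are
consistent with it versus inconsistent, the ratio of the two counts
estimating P(M0 | X) / P(M1 | X). The module also tallies where the root
falls across a posterior sample, picks the maximum-clade-credibility tree,
and roots unrooted trees on an outgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .treeio import Bipartition, PhyloTree, TreeSample, apply_burnin

__all__ = [
    "CladeHypothesis",
    "PosteriorOdds",
    "RootPlacementTable",
    "is_monophyletic",
    "is_sister_group",
    "posterior_model_odds",
    "root_bipartition",
    "root_frequency_table",
    "mcc_tree",
    "outgroup_root",
]


@dataclass(frozen=True)
class CladeHypothesis:
    """A named topological hypothesis over one or two focal taxon sets.

    ``predicate_kind`` is one of ``monophyly`` (one focal set forms a clade),
    ``sister_group`` (two focal sets are each monophyletic and jointly
    monophyletic) or ``negative_monophyly`` (the monophyly predicate is
    negated). ``background_constraints`` records taxon sets assumed
    monophyletic by the producing MCMC; they are bookkeeping only and are not
    re-checked here.
    """

    name: str
    focal_sets: tuple
    predicate_kind: str = "monophyly"
    background_constraints: tuple = ()

    def __post_init__(self):
        kinds = {"monophyly", "sister_group", "negative_monophyly"}
        if self.predicate_kind not in kinds:
            raise ValueError(f"unknown predicate kind {self.predicate_kind!r}")
        sets = [frozenset(s) for s in self.focal_sets]
        object.__setattr__(self, "focal_sets", tuple(sets))
        if self.predicate_kind == "sister_group" and len(sets) != 2:
            raise ValueError("sister_group needs exactly two focal sets")
        if self.predicate_kind != "sister_group" and len(sets) != 1:
            raise ValueError(f"{self.predicate_kind} needs exactly one focal set")
        for i, a in enumerate(sets):
            if not a:
                raise ValueError("focal sets must be non-empty")
            for b in sets[i + 1:]:
                if a & b:
                    raise ValueError("focal sets must be disjoint")

    def holds(self, tree: PhyloTree) -> bool:
        if self.predicate_kind == "monophyly":
            return is_monophyletic(tree, self.focal_sets[0])
        if self.predicate_kind == "negative_monophyly":
            return not is_monophyletic(tree, self.focal_sets[0])
        return is_sister_group(tree, self.focal_sets[0], self.focal_sets[1])


@dataclass(frozen=True)
class PosteriorOdds:
    """Counts of hypothesis-consistent vs -inconsistent posterior trees.

    ``odds`` is the ratio of posterior model masses
    n_consistent / n_inconsistent (+inf when nothing is inconsistent);
    ``odds_vs_total`` = n_consistent / n_total is also reported because both
    denominators appear in published tables of this quantity.
    """

    n_consistent: int
    n_inconsistent: int

    @property
    def n_total(self) -> int:
        return self.n_consistent + self.n_inconsistent

    @property
    def odds(self) -> float:
        if self.n_inconsistent == 0:
            return math.inf
        return self.n_consistent / self.n_inconsistent

    @property
    def odds_vs_total(self) -> float:
        return self.n_consistent / self.n_total

    @property
    def frequency_percent(self) -> float:
        return 100.0 * self.n_consistent / self.n_total


def _node_sets(tree: PhyloTree):
    sets = tree.leaf_sets()
    return sets, sets[tree.root]


def is_monophyletic(tree: PhyloTree, taxa) -> bool:
    """Does ``taxa`` form a clade (rooted) / a split (unrooted) of the tree?

    Singleton sets and the full taxon set are monophyletic by convention.
    """
    taxa = frozenset(taxa)
    if not taxa:
        raise ValueError("empty taxon set")
    sets, all_taxa = _node_sets(tree)
    missing = taxa - all_taxa
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    if len(taxa) == 1 or taxa == all_taxa:
        return True
    node_sets = set(sets.values())
    if taxa in node_sets:
        return True
    if not tree.rooted:
        # an unrooted split may be stored as the complementary clade
        return (all_taxa - taxa) in node_sets
    return False


def is_sister_group(tree: PhyloTree, set_a, set_b) -> bool:
    """Are the two sets each monophyletic and together a clade (sisters)?"""
    set_a, set_b = frozenset(set_a), frozenset(set_b)
    if set_a & set_b:
        raise ValueError("sister-group sets must be disjoint")
    return (
        is_monophyletic(tree, set_a)
        and is_monophyletic(tree, set_b)
        and is_monophyletic(tree, set_a | set_b)
    )


def posterior_model_odds(
    sample: TreeSample, hyp: CladeHypothesis, burnin: float | None = None
) -> PosteriorOdds:
    """Count posterior trees consistent with a topological hypothesis.

    Every post-burn-in tree is evaluated with the hypothesis predicate; the
    resulting counts estimate the posterior odds of the constrained model
    against its complement.
    """
    if burnin is not None:
        sample = apply_burnin(sample, burnin)
    if len(sample) == 0:
        raise ValueError("empty tree sample")
    n_yes = sum(1 for tree in sample if hyp.holds(tree))
    return PosteriorOdds(n_consistent=n_yes, n_inconsistent=len(sample) - n_yes)


def root_bipartition(tree: PhyloTree) -> Bipartition:
    """The canonical split between the two subtrees under a binary root."""
    children = tree.root.child_nodes()
    if len(children) != 2:
        raise ValueError(
            f"root bipartition needs a binary root; root has {len(children)} children"
        )
    sets, all_taxa = _node_sets(tree)
    return Bipartition.from_split(sets[children[0]], all_taxa)


@dataclass
class RootPlacementTable:
    """Tally of root positions (root bipartitions) across a posterior sample."""

    entries: list  # (Bipartition, count, frequency), sorted
    n_trees: int

    def frequencies(self) -> dict:
        return {bip: freq for bip, _, freq in self.entries}

    def to_rows(self):
        """Rows (smaller-side members, count, frequency) for tabular output."""
        rows = []
        for bip, count, freq in self.entries:
            side = min((bip.side_a, bip.side_b), key=lambda s: (len(s), sorted(s)))
            rows.append((",".join(sorted(side)), count, freq))
        return rows


def root_frequency_table(sample: TreeSample, burnin: float | None = None) -> RootPlacementTable:
    """How often each root placement was sampled during the MCMC.

    Placements are equivalence classes of root bipartitions (branch lengths
    ignored). Entries are sorted by descending frequency, ties broken by the
    lexicographically smallest member set.
    """
    if burnin is not None:
        sample = apply_burnin(sample, burnin)
    if len(sample) == 0:
        raise ValueError("empty tree sample")
    counts = {}
    for i, tree in enumerate(sample):
        if not tree.rooted:
            raise ValueError(f"tree {i} in the sample is unrooted")
        bip = root_bipartition(tree)
        counts[bip] = counts.get(bip, 0) + 1
    n = len(sample)
    entries = sorted(
        ((bip, c, c / n) for bip, c in counts.items()),
        key=lambda e: (-e[1], sorted(e[0].side_a)),
    )
    return RootPlacementTable(entries=entries, n_trees=n)


def mcc_tree(sample: TreeSample, burnin: float | None = None) -> PhyloTree:
    """The sampled tree maximizing the product of its clades' credibilities.

    Clade frequencies are estimated from the sample itself; each tree is
    scored by the sum of log clade frequencies over its non-trivial clades
    (sizes 2 .. n-1). Ties go to the earliest tree in sample order.
    """
    if burnin is not None:
        sample = apply_burnin(sample, burnin)
    if len(sample) == 0:
        raise ValueError("empty tree sample")
    n = len(sample)
    clade_counts = {}
    tree_clades = []
    for tree in sample:
        clades = tree.clades()
        tree_clades.append(clades)
        for c in clades:
            clade_counts[c] = clade_counts.get(c, 0) + 1
    best_idx, best_score = 0, -math.inf
    for i, clades in enumerate(tree_clades):
        score = sum(math.log(clade_counts[c] / n) for c in clades)
        if score > best_score:
            best_idx, best_score = i, score
    return sample.trees[best_idx]


def outgroup_root(tree: PhyloTree, outgroup) -> PhyloTree:
    """Root an unrooted tree on the edge separating ``outgroup`` from the rest.

    The attachment branch's length is split evenly between the two root
    children. The outgroup must be a single taxon or correspond to an
    existing bipartition of the tree.
    """
    outgroup = frozenset(outgroup)
    work = tree.copy()
    sets = work.leaf_sets()
    all_taxa = sets[work.root]
    if not outgroup or not outgroup < all_taxa:
        raise ValueError("outgroup must be a non-empty proper subset of the taxa")
    target = None
    for node, s in sets.items():
        if node is work.root:
            continue
        if s == outgroup or s == all_taxa - outgroup:
            target = node
            break
    if target is None:
        raise ValueError(
            "outgroup does not correspond to a bipartition of the tree"
        )
    edge = target.edge
    if edge.length is None:
        work.dendropy_tree.reroot_at_edge(edge)
    else:
        half = edge.length / 2.0
        work.dendropy_tree.reroot_at_edge(edge, length1=half, length2=half)
    # dendropy may leave the old root as a degree-2 node; remove it
    work.dendropy_tree.suppress_unifurcations()
    return PhyloTree(work.dendropy_tree, rooted=True)
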
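"""Synthetic trees, alignments, posterior samples and marginal-likelihood runs.

Every downstream stage (topology predicates, posterior odds, root-frequency
tables, the likelihood engine, Bayes-factor aggregation) gets a generator
here that produces data with known ground truth:

* pure-birth (Yule) trees with exchangeable tip labels,
* amino-acid alignments evolved along a known tree under LG(+Gamma)(+I),
* posterior-like tree samples in which a focal clade appears with a chosen
  probability, and root positions follow a chosen distribution,
* replicate stepping-stone log marginals as a true value plus noise.

All generators are reproducible: each operation derives its own random
stream from ``(seed, operation tag)``, so adding one generator call to a
script does not shift the draws of the others.
"""

from __future__ import annotations

import math

import dendropy
import numpy as np

from .margliks import MarginalRunSet
from .phylolik import AMINO_ACIDS, AminoAlignment, SubstitutionModel, _eigen_for
from .topotest import CladeHypothesis, outgroup_root
from .treeio import PhyloTree, TreeSample

__all__ = [
    "simulate_yule_tree",
    "simulate_alignment",
    "simulate_tree_sample",
    "simulate_root_sample",
    "simulate_marginal_runs",
]

# per-operation stream tags (arbitrary, fixed constants)
_TAG_YULE = 101
_TAG_ALN = 202
_TAG_SAMPLE = 303
_TAG_ROOT = 404
_TAG_MARGINAL = 505


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([int(seed) % (2**31), tag])


def _attach_children(parent: dendropy.Node, subtrees, tns, lengths):
    for sub, length in subtrees:
        node = _build_node(sub, tns, lengths)
        node.edge.length = length
        parent.add_child(node)


def _build_node(nested, tns, lengths) -> dendropy.Node:
    node = dendropy.Node()
    if isinstance(nested, tuple):
        for sub in nested:
            child = _build_node(sub, tns, lengths)
            child.edge.length = next(lengths)
            node.add_child(child)
    else:
        node.taxon = tns.require_taxon(label=nested)
    return node


def _tree_from_nested(nested, tns, lengths, rooted=True) -> PhyloTree:
    """Build a PhyloTree from nested label tuples; ``lengths`` yields branch
    lengths in construction (pre-order child) order."""
    dtree = dendropy.Tree(taxon_namespace=tns)
    root = _build_node(nested, tns, lengths)
    dtree.seed_node = root
    return PhyloTree(dtree, rooted=rooted)


def simulate_yule_tree(n_taxa: int, birth_rate: float, seed: int) -> PhyloTree:
    """A pure-birth tree conditioned on ``n_taxa`` extant tips.

    Starting from the root's two lineages, the waiting time while k lineages
    exist is Exponential(k * birth_rate); the tree is cut one waiting time
    after the n-th tip appears, so the expected root height is
    sum_{k=2..n} 1/(k * birth_rate). Tip labels T1..Tn are assigned in random
    order (exchangeability).
    """
    if n_taxa < 2:
        raise ValueError("need at least 2 taxa")
    if birth_rate <= 0:
        raise ValueError("birth rate must be positive")
    rng = _rng(seed, _TAG_YULE)
    tns = dendropy.TaxonNamespace()
    dtree = dendropy.Tree(taxon_namespace=tns)
    root = dtree.seed_node
    now = 0.0
    active = []
    for _ in range(2):
        child = dendropy.Node()
        child.birth_time = now
        root.add_child(child)
        active.append(child)
    while len(active) < n_taxa:
        now += rng.exponential(1.0 / (birth_rate * len(active)))
        idx = rng.integers(len(active))
        parent = active.pop(idx)
        parent.edge.length = now - parent.birth_time
        for _ in range(2):
            child = dendropy.Node()
            child.birth_time = now
            parent.add_child(child)
            active.append(child)
    now += rng.exponential(1.0 / (birth_rate * n_taxa))
    labels = [f"T{i + 1}" for i in range(n_taxa)]
    rng.shuffle(labels)
    for node, label in zip(active, labels):
        node.edge.length = now - node.birth_time
        node.taxon = tns.require_taxon(label=label)
    for node in dtree.preorder_node_iter():
        if hasattr(node, "birth_time"):
            del node.birth_time
    return PhyloTree(dtree, rooted=True)


def simulate_alignment(tree: PhyloTree, model: SubstitutionModel, length: int,
                       seed: int) -> AminoAlignment:
    """Evolve an amino-acid alignment along ``tree`` under ``model``.

    Each site is assigned to the invariant class with probability
    ``p_invariant``, otherwise to a uniform gamma rate category; the root
    residue is drawn from the stationary frequencies and propagated edge by
    edge with the model's transition probabilities.
    """
    if length < 1:
        raise ValueError("alignment length must be positive")
    rng = _rng(seed, _TAG_ALN)
    eigen = _eigen_for(model)
    rates = model.category_rates()
    ncat = len(rates)
    site_rates = rates[rng.integers(ncat, size=length)]
    if model.p_invariant > 0:
        invariant = rng.random(length) < model.p_invariant
        site_rates = np.where(invariant, 0.0, site_rates)
    pi = model.frequencies
    states = {id(tree.root): rng.choice(20, size=length, p=pi)}
    unique_rates = np.unique(site_rates)
    for node in tree.dendropy_tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        t = node.edge.length
        if t is None:
            raise ValueError("all branch lengths are required for simulation")
        parent_states = states[id(node.parent_node)]
        child = np.empty(length, dtype=np.int64)
        for r in unique_rates:
            mask = site_rates == r
            if r == 0.0 or t == 0.0:
                child[mask] = parent_states[mask]
                continue
            p = eigen.probs(t * r)
            cum = np.cumsum(p[parent_states[mask]], axis=1)
            u = rng.random(mask.sum())
            child[mask] = (u[:, None] > cum).sum(axis=1)
        states[id(node)] = child
    taxa, seqs = [], []
    for leaf in tree.dendropy_tree.leaf_node_iter():
        taxa.append(leaf.taxon.label)
        seqs.append("".join(AMINO_ACIDS[c] for c in states[id(leaf)]))
    return AminoAlignment(taxa, seqs)


def _random_rooted_nested(labels, rng):
    """Random rooted binary topology by sequential random joins."""
    items = list(labels)
    rng.shuffle(items)
    while len(items) > 1:
        i, j = sorted(rng.choice(len(items), size=2, replace=False))
        merged = (items[i], items[j])
        items = [x for k, x in enumerate(items) if k not in (i, j)]
        items.append(merged)
    return items[0]


def _lengths(rng, scale=0.1):
    while True:
        yield float(rng.exponential(scale))


def simulate_tree_sample(hypothesis, clade_probability: float, n_trees: int,
                         seed: int, extra_taxa=(), max_attempts: int = 10_000) -> TreeSample:
    """A posterior-like sample in which a focal hypothesis holds with a
    chosen probability.

    ``hypothesis`` is a :class:`~phylohypo.topotest.CladeHypothesis` (or one
    or two taxon sets, interpreted as monophyly / sister-group). Each emitted
    rooted tree independently satisfies the hypothesis with probability
    ``clade_probability``: satisfying trees are built by construction
    (focal subtrees joined, then attached inside a random tree on the
    remaining taxa), non-satisfying trees by rejection sampling of
    unconstrained random topologies (capped at ``max_attempts`` draws).
    """
    if isinstance(hypothesis, CladeHypothesis):
        hyp = hypothesis
    else:
        sets = [frozenset(s) for s in hypothesis]
        if len(sets) == 1:
            hyp = CladeHypothesis("clade", tuple(sets), "monophyly")
        else:
            hyp = CladeHypothesis("sisters", tuple(sets), "sister_group")
    if not (0 <= clade_probability <= 1):
        raise ValueError("clade probability must be in [0, 1]")
    focal = frozenset().union(*hyp.focal_sets)
    all_taxa = sorted(focal | frozenset(extra_taxa))
    rest = sorted(set(all_taxa) - focal)
    if not rest:
        raise ValueError(
            "the focal clade equals the full taxon set; the hypothesis can "
            "never be false — add extra_taxa"
        )
    rng = _rng(seed, _TAG_SAMPLE)
    tns = dendropy.TaxonNamespace()
    placeholder = "@clade@"

    def constrained_draw():
        if hyp.predicate_kind == "sister_group":
            a, b = hyp.focal_sets
            sub = (_random_rooted_nested(sorted(a), rng),
                   _random_rooted_nested(sorted(b), rng))
        else:
            sub = _random_rooted_nested(sorted(focal), rng)
        frame = _random_rooted_nested(rest + [placeholder], rng)

        def substitute(x):
            if isinstance(x, tuple):
                return tuple(substitute(c) for c in x)
            return sub if x == placeholder else x

        return substitute(frame)

    trees = []
    for _ in range(n_trees):
        if rng.random() < clade_probability:
            nested = constrained_draw()
            tree = _tree_from_nested(nested, tns, _lengths(rng))
        else:
            for _attempt in range(max_attempts):
                nested = _random_rooted_nested(all_taxa, rng)
                tree = _tree_from_nested(nested, tns, _lengths(rng))
                if not hyp.holds(tree):
                    break
            else:
                raise RuntimeError(
                    "could not draw a hypothesis-violating tree in "
                    f"{max_attempts} attempts"
                )
        trees.append(tree)
    return TreeSample(trees=trees, source=f"synthetic(p={clade_probability})")


def simulate_root_sample(base_tree: PhyloTree, root_distribution, n_trees: int,
                         seed: int) -> TreeSample:
    """Root a base tree on edges drawn from a placement distribution.

    ``root_distribution`` is a list of ``(taxon_set, probability)`` pairs;
    each taxon set must identify an edge of the base tree (a split side or a
    single leaf). Probabilities must sum to 1.
    """
    placements = [(frozenset(side), float(p)) for side, p in root_distribution]
    total = sum(p for _, p in placements)
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"root distribution sums to {total}, not 1")
    rooted = []
    for side, _ in placements:
        rooted.append(outgroup_root(base_tree, side))  # validates the edge
    rng = _rng(seed, _TAG_ROOT)
    probs = np.array([p for _, p in placements])
    draws = rng.choice(len(placements), size=n_trees, p=probs)
    trees = [rooted[k].copy() for k in draws]
    return TreeSample(trees=trees, source="synthetic-root-sample")


def simulate_marginal_runs(true_ln_ml: float, run_sd: float, n_runs: int,
                           seed: int, model_name: str = "model") -> MarginalRunSet:
    """Replicate log marginal likelihoods: true value + Normal(0, run_sd) noise."""
    if run_sd < 0:
        raise ValueError("run_sd must be non-negative")
    if n_runs < 1:
        raise ValueError("need at least one run")
    rng = _rng(seed, _TAG_MARGINAL)
    runs = true_ln_ml + rng.normal(0.0, run_sd, size=n_runs)
    return MarginalRunSet(model_name=model_name, run_log_marginals=tuple(runs))
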
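"""Diversity-maximizing taxon subsampling on group trees.

Reduces a large tree to a fixed number of representative leaves while
keeping as much phylogenetic diversity as possible: repeatedly find the
closest leaf pair (smallest patristic distance) and drop one of the two
until the target count remains. The default, deterministic rule drops the
less peripheral member of the pair (the one with the smaller total distance
to all remaining leaves, ties resolved by dropping the lexicographically
larger label); a seeded random mode drops a uniformly chosen member instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .treeio import PhyloTree, patristic_matrix

__all__ = ["GroupedTaxa", "diversity_subsample", "subsample_groups", "prune_to_taxa"]


@dataclass
class GroupedTaxa:
    """Per-group trees plus a taxon -> group label map."""

    trees: dict  # group label -> PhyloTree
    group_of: dict  # taxon label -> group label

    def __post_init__(self):
        for group, tree in self.trees.items():
            for taxon in tree.taxa:
                assigned = self.group_of.get(taxon)
                if assigned is None:
                    raise ValueError(f"taxon {taxon!r} has no group assignment")
                if assigned != group:
                    raise ValueError(
                        f"taxon {taxon!r} is assigned to group {assigned!r} "
                        f"but appears in the tree of {group!r}"
                    )


def diversity_subsample(tree: PhyloTree, target: int, seed: int | None = None) -> frozenset:
    """Greedy diversity-preserving reduction of a tree to ``target`` leaves.

    With ``seed=None`` the deterministic drop rule is used; an integer seed
    switches to the randomized variant (drop a random member of the closest
    pair).
    """
    if target < 2:
        raise ValueError("target must be at least 2")
    labels = sorted(tree.taxa)
    if target > len(labels):
        raise ValueError(
            f"target {target} exceeds the {len(labels)} leaves of the tree"
        )
    dist = patristic_matrix(tree).loc[labels, labels].to_numpy()
    rng = np.random.default_rng(seed) if seed is not None else None
    alive = list(range(len(labels)))
    while len(alive) > target:
        sub = dist[np.ix_(alive, alive)]
        np.fill_diagonal(sub, np.inf)
        flat = np.argmin(sub)
        i, j = np.unravel_index(flat, sub.shape)
        a, b = alive[i], alive[j]
        if rng is not None:
            drop = a if rng.integers(2) == 0 else b
        else:
            tot_a = sub[i].copy()
            tot_b = sub[j].copy()
            tot_a[np.isinf(tot_a)] = 0.0
            tot_b[np.isinf(tot_b)] = 0.0
            sa, sb = tot_a.sum(), tot_b.sum()
            if sa < sb:
                drop = a
            elif sb < sa:
                drop = b
            else:
                drop = a if labels[a] > labels[b] else b
        alive.remove(drop)
    return frozenset(labels[k] for k in alive)


def subsample_groups(grouped: GroupedTaxa, per_group_target: int,
                     seed: int | None = None) -> dict:
    """Subsample each group's tree independently to ``per_group_target`` leaves.

    Groups at or below the target are kept whole. Returns a map
    group -> retained taxon frozenset.
    """
    out = {}
    for group in sorted(grouped.trees):
        tree = grouped.trees[group]
        if tree.n_leaves == 0:
            raise ValueError(f"group {group!r} is empty")
        if tree.n_leaves <= per_group_target:
            out[group] = frozenset(tree.taxa)
        else:
            group_seed = None
            if seed is not None:
                group_seed = int(
                    np.random.SeedSequence(
                        [seed, abs(hash(group)) % (2**31)]
                    ).generate_state(1)[0] % (2**31)
                )
            out[group] = diversity_subsample(tree, per_group_target, group_seed)
    return out


def prune_to_taxa(tree: PhyloTree, keep) -> PhyloTree:
    """Prune a tree down to the given leaf set (patristic distances among the
    kept leaves are unchanged)."""
    keep = set(keep)
    missing = keep - tree.taxa
    if missing:
        raise ValueError(f"taxa not in tree: {sorted(missing)}")
    pruned = tree.copy()
    d = pruned.dendropy_tree
    d.retain_taxa_with_labels(sorted(keep))
    d.suppress_unifurcations()
    return PhyloTree(d, rooted=None)
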
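import itertools
import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.stats import gamma as gamma_dist

from phylohypo import parse_newick
from phylohypo import phylolik as pl
from phylohypo import synthgen as sg
from phylohypo import topotest as tt
from conftest import random_model


# ---------------------------------------------------------------------------
# independent brute-force likelihood oracle


def brute_force_loglik(tree, aln, model):
    """Exhaustive summation over internal-node states (oracle).

    Only feasible for <= 4 leaves; written against the plain mixture
    definition, sharing nothing with the pruning implementation.
    """
    nodes = list(tree.dendropy_tree.preorder_node_iter())
    internal = [n for n in nodes if not n.is_leaf()]
    leaves = [n for n in nodes if n.is_leaf()]
    root = nodes[0]
    pi = model.frequencies
    rates = model.category_rates()
    p_inv = model.p_invariant
    row = {leaf.taxon.label: aln.taxa.index(leaf.taxon.label) for leaf in leaves}
    total = 0.0
    for site in range(aln.length):
        observed = {
            leaf: aln.codes[row[leaf.taxon.label], site] for leaf in leaves
        }
        lik_var = 0.0
        for r in rates:
            p_edge = {
                id(n): pl.transition_probs(model, n.edge.length * r)
                for n in nodes
                if n.parent_node is not None
            }
            site_sum = 0.0
            for states in itertools.product(range(20), repeat=len(internal)):
                assign = dict(zip((id(n) for n in internal), states))
                term = pi[assign[id(root)]]
                for n in nodes:
                    if n.parent_node is None:
                        continue
                    parent_state = assign[id(n.parent_node)]
                    if n.is_leaf():
                        code = observed[n]
                        if code < 0:
                            term *= 1.0  # missing: sums to one over states
                        else:
                            term *= p_edge[id(n)][parent_state, code]
                    else:
                        term *= p_edge[id(n)][parent_state, assign[id(n)]]
                site_sum += term
            lik_var += site_sum / len(rates)
        codes = [c for c in observed.values() if c >= 0]
        if len(codes) == 0:
            lik_inv = 1.0
        elif len(set(codes)) == 1:
            lik_inv = pi[codes[0]]
        else:
            lik_inv = 0.0
        total += math.log((1 - p_inv) * lik_var + p_inv * lik_inv)
    return total


def random_alignment(rng, taxa, length, with_gaps=False):
    letters = list(pl.AMINO_ACIDS)
    seqs = {}
    for t in taxa:
        chars = rng.choice(letters, size=length)
        if with_gaps:
            mask = rng.random(length) < 0.15
            chars = np.where(mask, "-", chars)
        seqs[t] = "".join(chars)
    return pl.AminoAlignment(list(taxa), seqs)


class TestRateMatrix:
    def test_uniform_model_gives_jc_like_matrix(self):
        s = np.ones((20, 20)) - np.eye(20)
        model = pl.SubstitutionModel(s, np.full(20, 0.05))
        q = pl.build_rate_matrix(model)
        off = q[~np.eye(20, dtype=bool)]
        assert np.allclose(off, 1.0 / 19.0)

    def test_stationarity_and_scaling(self, lg):
        q = pl.build_rate_matrix(lg)
        assert np.allclose(lg.frequencies @ q, 0.0, atol=1e-12)
        assert np.allclose(q.sum(axis=1), 0.0, atol=1e-12)
        assert -np.dot(lg.frequencies, np.diag(q)) == pytest.approx(1.0)

    def test_detailed_balance_on_random_models(self, rng):
        for _ in range(5):
            model = random_model(rng)
            q = pl.build_rate_matrix(model)
            flux = model.frequencies[:, None] * q
            assert np.allclose(flux, flux.T, atol=1e-12)


class TestDiscreteGamma:
    def test_single_category_is_rate_one(self):
        assert pl.discrete_gamma(0.7, 1).tolist() == [1.0]

    def test_large_shape_approaches_equal_rates(self):
        rates = pl.discrete_gamma(1e6, 4)
        assert np.allclose(rates, 1.0, atol=1e-2)

    @pytest.mark.parametrize("shape", [0.3, 0.5, 1.0, 2.0])
    def test_rates_match_quadrature_oracle(self, shape):
        n = 4
        bounds = np.concatenate(
            [[0.0], gamma_dist.ppf(np.arange(1, n) / n, a=shape, scale=1 / shape), [np.inf]]
        )
        expected = []
        for lo, hi in zip(bounds[:-1], bounds[1:]):
            mass, _ = quad(
                lambda x: x * gamma_dist.pdf(x, a=shape, scale=1 / shape), lo, hi
            )
            expected.append(n * mass)
        assert np.allclose(pl.discrete_gamma(shape, n), expected, atol=1e-6)

    def test_rates_average_to_one(self):
        for shape in (0.2, 0.9, 3.7):
            assert pl.discrete_gamma(shape, 8).mean() == pytest.approx(1.0)


class TestTransitionProbs:
    def test_zero_time_is_identity(self, lg):
        assert np.allclose(pl.transition_probs(lg, 0.0), np.eye(20))

    def test_long_time_reaches_stationarity(self, lg):
        p = pl.transition_probs(lg, 500.0)
        assert np.allclose(p, np.tile(lg.frequencies, (20, 1)), atol=1e-8)

    def test_semigroup_property_on_random_models(self, rng):
        for _ in range(5):
            model = random_model(rng)
            t1, t2 = rng.uniform(0.05, 1.0, size=2)
            p = pl.transition_probs(model, t1) @ pl.transition_probs(model, t2)
            assert np.allclose(p, pl.transition_probs(model, t1 + t2), atol=1e-10)

    def test_rows_are_distributions(self, lg):
        p = pl.transition_probs(lg, 0.37)
        assert np.all(p >= 0)
        assert np.allclose(p.sum(axis=1), 1.0)

    def test_negative_time_rejected(self, lg):
        with pytest.raises(ValueError):
            pl.transition_probs(lg, -0.1)


class TestTreeLogLikelihood:
    def test_two_taxon_closed_form(self, lg):
        tree = parse_newick("(A:0.3,B:0.7);")
        aln = pl.AminoAlignment(["A", "B"], ["W", "W"])
        w = pl._AA_INDEX["W"]
        expected = math.log(lg.frequencies[w] * pl.transition_probs(lg, 1.0)[w, w])
        assert pl.tree_log_likelihood(tree, aln, lg) == pytest.approx(expected)

    def test_three_leaf_brute_force(self, rng):
        tree = parse_newick("(A:0.2,B:0.5,C:0.3);")
        for _ in range(3):
            model = random_model(rng, gamma=True, invariant=True)
            aln = random_alignment(rng, ["A", "B", "C"], 5, with_gaps=True)
            assert pl.tree_log_likelihood(tree, aln, model) == pytest.approx(
                brute_force_loglik(tree, aln, model), abs=1e-8
            )

    def test_gaps_contribute_all_ones_partials(self, lg):
        tree = parse_newick("((A:0.2,B:0.3):0.1,(C:0.2,D:0.4):0.2);")
        full = pl.AminoAlignment(["A", "B", "C", "D"], ["K", "K", "-", "-"])
        reduced = pl.AminoAlignment(["A", "B"], ["K", "K"])
        # with C and D all-gaps the likelihood marginalizes to the A-B path
        sub = parse_newick("(A:0.2,B:0.3);")
        assert pl.tree_log_likelihood(tree, full, lg) == pytest.approx(
            pl.tree_log_likelihood(sub, reduced, lg)
        )

    def test_rerooting_invariance(self, lg_gamma_inv):
        tree = sg.simulate_yule_tree(6, 1.0, seed=12)
        aln = sg.simulate_alignment(tree, lg_gamma_inv, 40, seed=12)
        base = pl.tree_log_likelihood(tree, aln, lg_gamma_inv)
        for taxon in sorted(tree.taxa)[:3]:
            rerooted = tt.outgroup_root(tree, {taxon})
            assert pl.tree_log_likelihood(rerooted, aln, lg_gamma_inv) == pytest.approx(
                base, abs=1e-6
            )

    def test_missing_taxon_is_error(self, lg):
        tree = parse_newick("(A:0.1,B:0.1,C:0.1);")
        aln = pl.AminoAlignment(["A", "B"], ["K", "K"])
        with pytest.raises(ValueError, match="missing"):
            pl.tree_log_likelihood(tree, aln, lg)


class TestPartitions:
    def test_single_partition_equals_plain_likelihood(self, lg):
        tree = sg.simulate_yule_tree(5, 1.0, seed=3)
        aln = sg.simulate_alignment(tree, lg, 60, seed=3)
        scheme = pl.PartitionScheme.single(60, lg)
        assert pl.partitioned_log_likelihood(tree, aln, scheme) == pytest.approx(
            pl.tree_log_likelihood(tree, aln, lg)
        )

    def test_duplicated_partition_doubles_loglik(self, lg):
        tree = sg.simulate_yule_tree(5, 1.0, seed=4)
        half = sg.simulate_alignment(tree, lg, 30, seed=4)
        doubled = pl.AminoAlignment(
            half.taxa, {t: half.row(t) * 2 for t in half.taxa}
        )
        scheme = pl.PartitionScheme(
            [pl.Partition("p1", 0, 30, lg), pl.Partition("p2", 30, 60, lg)]
        )
        assert pl.partitioned_log_likelihood(tree, doubled, scheme) == pytest.approx(
            2 * pl.tree_log_likelihood(tree, half, lg)
        )

    def test_block_additivity_with_different_models(self, lg, lg_gamma_inv, rng):
        tree = sg.simulate_yule_tree(5, 1.0, seed=5)
        blocks = [
            sg.simulate_alignment(tree, lg, 20, seed=6),
            sg.simulate_alignment(tree, lg_gamma_inv, 25, seed=7),
        ]
        combined, scheme = pl.concatenate_alignments(blocks, names=["a", "b"])
        scheme = scheme.assign_models([lg, lg_gamma_inv])
        expected = pl.tree_log_likelihood(tree, blocks[0], lg) + pl.tree_log_likelihood(
            tree, blocks[1], lg_gamma_inv
        )
        assert pl.partitioned_log_likelihood(tree, combined, scheme) == pytest.approx(
            expected
        )

    def test_concatenation_gap_fills_missing_taxa(self):
        a = pl.AminoAlignment(["A", "B"], ["KR", "KR"])
        b = pl.AminoAlignment(["A", "C"], ["WW", "WW"])
        combined, scheme = pl.concatenate_alignments([a, b])
        assert combined.length == 4
        assert combined.row("B") == "KR--"
        assert combined.row("C") == "--WW"
        assert [(p.start, p.end) for p in scheme.partitions] == [(0, 2), (2, 4)]

    def test_empty_block_list_is_error(self):
        with pytest.raises(ValueError):
            pl.concatenate_alignments([])

    def test_partition_file_parsing_one_based_inclusive(self):
        scheme = pl.parse_partition_file("mcp = 1-100\natpase = 101-150\n")
        assert [(p.start, p.end) for p in scheme.partitions] == [(0, 100), (100, 150)]


class TestBranchOptimization:
    def test_loglik_never_decreases_and_improves(self, lg):
        true = sg.simulate_yule_tree(5, 1.0, seed=21)
        aln = sg.simulate_alignment(true, lg, 300, seed=21)
        start = parse_newick(
            pl._topology_newick(next(pl.enumerate_topologies(sorted(true.taxa))), 0.05)
        )
        scheme = pl.PartitionScheme.single(aln.length, lg)
        l0 = pl.tree_log_likelihood(start, aln, lg)
        _, l1 = pl.optimize_branch_lengths(start, aln, scheme)
        assert l1 >= l0

    def test_already_optimal_lengths_unchanged(self, lg):
        tree = sg.simulate_yule_tree(5, 1.0, seed=22)
        aln = sg.simulate_alignment(tree, lg, 500, seed=22)
        scheme = pl.PartitionScheme.single(aln.length, lg)
        opt_tree, l1 = pl.optimize_branch_lengths(tree, aln, scheme)
        _, l2 = pl.optimize_branch_lengths(opt_tree, aln, scheme)
        assert l2 == pytest.approx(l1, abs=1e-3)

    def test_branch_length_recovery_on_long_alignment(self, lg):
        true = parse_newick("((A:0.3,B:0.5):0.25,(C:0.4,D:0.2):0.15);")
        aln = sg.simulate_alignment(true, lg, 5000, seed=23)
        start = parse_newick("((A:0.1,B:0.1):0.1,(C:0.1,D:0.1):0.1);")
        scheme = pl.PartitionScheme.single(aln.length, lg)
        fitted, _ = pl.optimize_branch_lengths(start, aln, scheme)
        from phylohypo import patristic_matrix

        want = patristic_matrix(true)
        got = patristic_matrix(fitted)
        labels = sorted(true.taxa)
        ratio = got.loc[labels, labels].to_numpy() / np.where(
            want.loc[labels, labels].to_numpy() == 0, 1, want.loc[labels, labels].to_numpy()
        )
        off = ratio[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off - 1.0) < 0.15)


class TestConstrainedSearch:
    def test_topology_counts(self):
        assert sum(1 for _ in pl.enumerate_topologies("ABCD")) == 3
        assert sum(1 for _ in pl.enumerate_topologies("ABCDE")) == 15
        assert sum(1 for _ in pl.enumerate_topologies("ABCDEF")) == 105

    def test_four_taxon_constraint_selects_one_topology(self, lg):
        hyp = tt.CladeHypothesis("m", (frozenset({"A", "B"}),), "monophyly")
        passing = []
        for top in pl.enumerate_topologies("ABCD"):
            splits, all_taxa = pl._topology_splits(top)
            if pl._hypothesis_on_splits(hyp, splits, all_taxa):
                passing.append(top)
        assert len(passing) == 1

    def test_negative_constraint_never_beats_unconstrained(self, lg):
        true = parse_newick("((A:0.3,B:0.3):0.3,(C:0.3,D:0.3):0.05);")
        aln = sg.simulate_alignment(true, lg, 300, seed=31)
        scheme = pl.PartitionScheme.single(aln.length, lg)
        hyp = tt.CladeHypothesis("m", (frozenset({"A", "B"}),), "monophyly")
        _, l_unconstrained = pl.constrained_best_tree(aln, scheme, None)
        _, l_negative = pl.constrained_best_tree(aln, scheme, hyp, negative=True)
        assert l_negative <= l_unconstrained + 1e-6

    def test_generating_topology_recovered_with_strong_signal(self, lg):
        true = parse_newick(
            "(((A:0.2,B:0.2):0.3,(C:0.2,D:0.2):0.3):0.3,(E:0.2,F:0.2):0.2);"
        )
        aln = sg.simulate_alignment(true, lg, 1000, seed=32)
        scheme = pl.PartitionScheme.single(aln.length, lg)
        hyp = tt.CladeHypothesis(
            "s", (frozenset({"A", "B"}), frozenset({"C", "D"})), "sister_group"
        )
        tree_c, l_c = pl.constrained_best_tree(aln, scheme, hyp)
        from phylohypo import bipartitions

        true_splits = bipartitions(true)
        assert bipartitions(tree_c) == true_splits

    def test_too_many_taxa_rejected(self, lg):
        taxa = [f"T{i}" for i in range(9)]
        aln = pl.AminoAlignment(taxa, ["K"] * 9)
        scheme = pl.PartitionScheme.single(1, lg)
        with pytest.raises(ValueError, match="8 taxa"):
            pl.constrained_best_tree(aln, scheme, None)


class TestModelSpecs:
    def test_spec_string_parsing(self):
        m = pl.model_from_spec("LG+G4+I", gamma_shape=0.6, p_invariant=0.2)
        assert m.gamma_shape == 0.6
        assert m.n_categories == 4
        assert m.p_invariant == 0.2

    def test_plus_f_uses_observed_frequencies(self):
        aln = pl.AminoAlignment(["A", "B"], ["KKKK", "KKKR"])
        m = pl.model_from_spec("LG+F", alignment=aln)
        k = pl._AA_INDEX["K"]
        assert m.frequencies[k] == max(m.frequencies)

    def test_unknown_model_rejected(self):
        with pytest.raises(ValueError):
            pl.model_from_spec("WAG+G4")

    def test_parameter_count_accounting(self, lg):
        scheme = pl.PartitionScheme.single(100, pl.lg_model(gamma_shape=1.0, p_invariant=0.1))
        # 2n-3 branches + alpha + p_inv
        assert pl.count_free_parameters(6, scheme) == 9 + 2
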
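import numpy as np
import pytest

import phyloca as pc
from phyloca.errors import HypothesisError, NewickError
from phyloca.seqio import AMINO_ACIDS
from phyloca.treelik import (
    PruningEngine,
    empirical_frequencies,
    fit_hypothesis,
    leaf_tree,
)

from conftest import brute_force_loglik


class TestNewick:
    def test_two_leaf_lengths(self):
        t = pc.read_newick("(A:0.1,B:0.2);")
        assert sorted(t.leaf_names()) == ["A", "B"]
        lengths = {n.label: n.length for n in t.leaves()}
        assert lengths == {"A": 0.1, "B": 0.2}

    def test_four_leaf_edge_count(self):
        t = pc.read_newick("((A:1,B:1):1,(C:1,D:1):1);")
        edges = [n for n in t.postorder() if n is not t.root]
        # rooted representation: 6 edges; unrooted free parameters: 5
        assert len(edges) == 6
        from phyloca.treelik import free_edge_groups

        assert len(free_edge_groups(t.copy())) == 5

    def test_roundtrip(self):
        text = "((A:0.1,B:0.2):0.05,(C:0.3,D:0.4):0.06);"
        t = pc.read_newick(text)
        again = pc.read_newick(pc.write_newick(t))
        assert sorted(again.leaf_names()) == sorted(t.leaf_names())
        assert np.isclose(again.total_length(), t.total_length())

    def test_unbalanced_parentheses(self):
        with pytest.raises(NewickError):
            pc.read_newick("(A,(B);")


class TestStarTree:
    def test_three_taxa(self):
        t = pc.star_tree(["A", "B", "C"], 0.2)
        assert t.is_star and t.n_leaves == 3
        assert len(t.root.children) == 3

    def test_too_few_taxa(self):
        with pytest.raises(HypothesisError):
            pc.star_tree(["A"])

    def test_equal_branch_star_likelihood_is_exchangeable(self, poisson, rng):
        taxa = list("ABCDEF")
        t = pc.star_tree(taxa, 0.4)
        a = pc.simulate_on_tree(t, poisson, 40, seed=5)
        base = pc.loglik(t, a, poisson)
        for _ in range(3):
            perm = rng.permutation(taxa)
            t2 = pc.star_tree(list(perm), 0.4)
            assert np.isclose(pc.loglik(t2, a, poisson), base, atol=1e-9)


class TestLoglik:
    def test_single_leaf_is_stationary_term(self, wag):
        a = pc.Alignment(("A",), ("ACD-X",))
        expected = sum(
            np.log(wag.pi[AMINO_ACIDS.index(c)]) for c in "ACD"
        )
        assert np.isclose(pc.loglik(leaf_tree("A"), a, wag), expected)

    def test_zero_branches_identical_sequences(self, poisson):
        t = pc.read_newick("(A:0,B:0);")
        a = pc.Alignment(("A", "B"), ("ACD", "ACD"))
        expected = 3 * np.log(1 / 20)
        assert np.isclose(pc.loglik(t, a, poisson), expected, atol=1e-9)

    @pytest.mark.parametrize("newick,rows", [
        ("((A:0.12,B:0.3):0.07,(C:0.2,D:0.05):0.11);",
         ("ACD", "R-W", "XKC", "AAC")),
        ("(((A:0.1,B:0.2):0.1,C:0.3):0.05,(D:0.15,E:0.25):0.1);",
         ("ACDEF", "ACDEW", "AC-EF", "GCDEF", "AXDEF")),
    ])
    def test_pruning_equals_exhaustive_enumeration(self, wag_gamma, newick, rows):
        t = pc.read_newick(newick)
        names = tuple(sorted(t.leaf_names()))
        a = pc.Alignment(names, rows)
        assert np.isclose(
            pc.loglik(t, a, wag_gamma), brute_force_loglik(t, a, wag_gamma),
            atol=1e-9,
        )

    def test_invariant_under_rerooting(self, wag_gamma):
        # same unrooted tree written with two different rootings
        a = pc.Alignment(tuple("ABCD"), ("ACDE", "AFDE", "GCWE", "ACDK"))
        t1 = pc.read_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
        t2 = pc.read_newick("(A:0.1,(B:0.2,((C:0.3,D:0.1):0.07):0.05):0.0);")
        # t2: rooted at the A edge; total path lengths identical
        l1, l2 = pc.loglik(t1, a, wag_gamma), pc.loglik(t2, a, wag_gamma)
        assert np.isclose(l1, l2, atol=1e-9)

    def test_topology_change_changes_likelihood(self, wag):
        # same total tree length, different topology (six taxa)
        a = pc.simulate_on_tree(
            pc.read_newick("(((A:.2,B:.2):.1,C:.3):.1,((D:.2,E:.2):.1,F:.3):.1);"),
            wag, 200, seed=11)
        t1 = pc.read_newick("(((A:.2,B:.2):.1,C:.3):.1,((D:.2,E:.2):.1,F:.3):.1);")
        t2 = pc.read_newick("(((A:.2,D:.2):.1,C:.3):.1,((B:.2,E:.2):.1,F:.3):.1);")
        assert abs(pc.loglik(t1, a, wag) - pc.loglik(t2, a, wag)) > 1.0

    def test_missing_leaf_sequence_rejected(self, wag):
        t = pc.read_newick("(A:0.1,Z:0.1);")
        a = pc.Alignment(("A", "B"), ("AC", "AC"))
        with pytest.raises(HypothesisError):
            pc.loglik(t, a, wag)


def test_engine_incremental_updates_match_fresh_evaluation(wag_gamma, rng):
    t = pc.read_newick("(((A:.2,B:.2):.1,C:.3):.1,((D:.2,E:.2):.1,F:.3):.1);")
    a = pc.simulate_on_tree(t, wag_gamma, 60, seed=3)
    eng = PruningEngine(t, a, wag_gamma)
    nodes = [n for n in eng.tree.postorder() if n is not eng.tree.root]
    for _ in range(25):
        node = nodes[rng.integers(len(nodes))]
        eng.set_length(node, float(rng.exponential(0.3)))
        assert np.isclose(eng.loglik(), pc.loglik(eng.tree, a, wag_gamma),
                          atol=1e-9)


class TestForest:
    def test_single_group_reduces_to_tree_likelihood(self, wag, small_alignment):
        t = pc.read_newick("((A:0.1,B:0.2):0.05,(C:0.3,D:0.1):0.07);")
        h = pc.AncestryHypothesis.common_ancestry(t)
        assert np.isclose(
            pc.forest_loglik(h, small_alignment, wag),
            pc.loglik(t, small_alignment, wag),
        )

    def test_two_groups_sum(self, wag, small_alignment):
        ta = pc.read_newick("(A:0.1,B:0.2);")
        tb = pc.read_newick("(C:0.3,D:0.1);")
        h = pc.AncestryHypothesis((("A", "B"), ("C", "D")), (ta, tb), "IA")
        expected = (
            pc.loglik(ta, small_alignment.restrict(["A", "B"]), wag)
            + pc.loglik(tb, small_alignment.restrict(["C", "D"]), wag)
        )
        assert np.isclose(pc.forest_loglik(h, small_alignment, wag), expected)

    def test_all_singletons_is_independent_residues(self, wag, small_alignment):
        h = pc.AncestryHypothesis(
            tuple((n,) for n in small_alignment.names),
            tuple(leaf_tree(n) for n in small_alignment.names),
        )
        expected = sum(
            np.log(wag.pi[AMINO_ACIDS.index(c)])
            for row in small_alignment.rows for c in row if c in AMINO_ACIDS
        )
        assert np.isclose(pc.forest_loglik(h, small_alignment, wag), expected)

    def test_incomplete_partition_rejected(self, wag, small_alignment):
        h = pc.AncestryHypothesis(
            (("A", "B"),), (pc.read_newick("(A:0.1,B:0.1);"),)
        )
        with pytest.raises(HypothesisError):
            pc.forest_loglik(h, small_alignment, wag)


class TestCountParameters:
    def _hyp(self, partition):
        groups = tuple(tuple(g) for g in partition)
        trees = tuple(
            leaf_tree(g[0]) if len(g) == 1 else pc.star_tree(g, 0.1)
            for g in groups
        )
        return pc.AncestryHypothesis(groups, trees)

    def test_common_ancestry_four_taxa(self):
        assert pc.count_parameters(self._hyp(["BEMP"])) == 25

    def test_one_plus_three_unrooted(self):
        assert pc.count_parameters(self._hyp(["E", "BMP"])) == 42

    def test_two_plus_two_conventions(self):
        h = self._hyp(["BE", "MP"])
        assert pc.count_parameters(h, "table2_compat") == 44
        assert pc.count_parameters(h, "unrooted") == 42

    def test_unknown_convention(self):
        with pytest.raises(HypothesisError):
            pc.count_parameters(self._hyp(["BEMP"]), "rooted")


def test_parse_partition():
    taxa = ("B", "E", "M", "P")
    assert pc.parse_partition("BE+MP", taxa) == (("B", "E"), ("M", "P"))
    assert pc.parse_partition("BEMP", taxa) == (("B", "E", "M", "P"),)
    assert pc.parse_partition("B,E+M,P", taxa) == (("B", "E"), ("M", "P"))
    with pytest.raises(HypothesisError):
        pc.parse_partition("BE+M", taxa)
    with pytest.raises(HypothesisError):
        pc.parse_partition("BE+MP+BE", ("B", "E", "M", "P"))


class TestOptimize:
    def test_recovers_two_leaf_branch_length(self, poisson):
        true_t = 0.3
        t = pc.read_newick(f"(A:{true_t/2},B:{true_t/2});")
        L = 10_000
        a = pc.simulate_on_tree(t, poisson, L, seed=7)
        res = pc.optimize_branch_lengths(t, a, poisson)
        fitted = res.tree.total_length()
        # Fisher information of the Poisson-model distance at t=0.3
        p_same = 0.05 + 0.95 * np.exp(-20 / 19 * true_t)
        dp = -np.exp(-20 / 19 * true_t)
        info = L * dp**2 * (1 / p_same + 1 / ((1 - p_same)))
        se = 1 / np.sqrt(info)
        assert abs(fitted - true_t) < 3 * se
        assert res.converged

    def test_identical_sequences_hit_lower_bound(self, poisson):
        t = pc.read_newick("(A:0.2,B:0.4);")
        a = pc.Alignment(("A", "B"), ("ACDEFG" * 10,) * 2)
        res = pc.optimize_branch_lengths(t, a, poisson)
        assert res.tree.total_length() < 1e-6

    def test_ml_dominates_generating_parameters(self, wag):
        t = pc.read_newick("((A:0.15,B:0.2):0.1,(C:0.25,D:0.1):0.12);")
        a = pc.simulate_on_tree(t, wag, 300, seed=9)
        res = pc.optimize_branch_lengths(t, a, wag)
        assert res.loglik >= pc.loglik(t, a, wag) - 1e-9


def test_fit_hypothesis_gives_each_group_its_own_frequencies(wag):
    t = pc.read_newick("((A:.2,B:.2):.5,(C:.2,D:.2):.5);")
    a = pc.simulate_on_tree(t, wag, 150, seed=13)
    h = pc.AncestryHypothesis(
        (("A", "B"), ("C", "D")),
        (pc.read_newick("(A:.2,B:.2);"), pc.read_newick("(C:.2,D:.2);")),
        "IA",
    )
    _, models, total = fit_hypothesis(h, a, wag, frequencies="empirical")
    assert len(models) == 2
    assert not np.allclose(models[0].pi, models[1].pi)
    expected0 = empirical_frequencies(a.restrict(["A", "B"]))
    assert np.allclose(models[0].pi, expected0)
    assert np.isfinite(total)


def test_enumerate_topologies_counts():
    assert len(pc.enumerate_topologies(list("ABCD"))) == 3
    assert len(pc.enumerate_topologies(list("ABCDE"))) == 15
    tops = pc.enumerate_topologies(list("ABCDEF"))
    assert len(tops) == 105
    assert all(sorted(t.leaf_names()) == list("ABCDEF") for t in tops)


def test_nj_topology_recovers_clear_split(wag):
    t = pc.read_newick("(((A:.1,B:.1):.3,C:.4):.3,((D:.1,E:.1):.3,F:.4):.3);")
    a = pc.simulate_on_tree(t, wag, 400, seed=21)
    nj = pc.nj_topology(a)
    # the AB cherry should be present: A and B separated from the rest
    ab = {"A", "B"}
    found = False

    def clades(node):
        if node.is_leaf:
            return {node.label}
        s = set()
        for c in node.children:
            s |= clades(c)
        return s
    for node in nj.postorder():
        if clades(node) == ab:
            found = True
    assert found
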
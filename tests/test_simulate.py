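import json

import numpy as np
import pytest
from scipy.stats import chisquare

import phyloca as pc
from phyloca.seqio import AMINO_ACIDS
from phyloca.simulate import PAIRINGS, SimulationSpec, progressive_align, realize
from phyloca.treelik import leaf_tree


class TestSimulateOnTree:
    def test_zero_branches_all_identical(self, wag):
        t = pc.read_newick("((A:0,B:0):0,(C:0,D:0):0);")
        a = pc.simulate_on_tree(t, wag, 100, seed=1)
        assert len(set(a.rows)) == 1

    def test_deterministic_under_seed(self, wag):
        t = pc.read_newick("(A:0.2,B:0.3);")
        assert pc.simulate_on_tree(t, wag, 50, seed=4) == pc.simulate_on_tree(
            t, wag, 50, seed=4)

    def test_saturation_identity_matches_stationary(self, wag):
        t = pc.read_newick("(A:500,B:500);")
        a = pc.simulate_on_tree(t, wag, 10_000, seed=2)
        ident = np.mean([c1 == c2 for c1, c2 in zip(*a.rows)])
        expected = (wag.pi**2).sum()
        se = np.sqrt(expected * (1 - expected) / 10_000)
        assert abs(ident - expected) < 3 * se

    def test_residue_frequencies_follow_stationary_distribution(self, wag):
        # one row is i.i.d. across sites under stationarity (taxa within a
        # column share the root state, so pooling rows would break the
        # chi-square independence assumption)
        t = pc.star_tree(list("ABCD"), 0.5)
        a = pc.simulate_on_tree(t, wag, 10_000, seed=3)
        counts = np.zeros(20)
        for c in a.rows[0]:
            counts[AMINO_ACIDS.index(c)] += 1
        stat = chisquare(counts, wag.pi * counts.sum())
        assert stat.pvalue > 0.01

    def test_gamma_categories_shared_across_tree(self):
        # strong rate heterogeneity: sites where A,B differ should be the
        # sites where C,D differ more often than independence predicts
        m = pc.SubstitutionModel(pc.load_matrix("poisson"),
                                 pc.discrete_gamma(0.05, 4))
        t = pc.read_newick("((A:0.5,B:0.5):0.01,(C:0.5,D:0.5):0.01);")
        a = pc.simulate_on_tree(t, m, 4000, seed=6)
        d1 = np.array([c1 != c2 for c1, c2 in zip(a.rows[0], a.rows[1])])
        d2 = np.array([c1 != c2 for c1, c2 in zip(a.rows[2], a.rows[3])])
        corr = np.corrcoef(d1, d2)[0, 1]
        assert corr > 0.1


class TestSimulateForest:
    def _hyp(self):
        return pc.AncestryHypothesis(
            (("A", "B"), ("C", "D")),
            (pc.read_newick("(A:0.2,B:0.2);"), pc.read_newick("(C:0.2,D:0.2);")),
            "IA",
        )

    def test_deterministic(self, wag):
        h = self._hyp()
        assert pc.simulate_forest(h, wag, 40, seed=1) == pc.simulate_forest(
            h, wag, 40, seed=1)

    def test_adding_group_does_not_perturb_first_group(self, wag):
        h2 = self._hyp()
        h3 = pc.AncestryHypothesis(
            h2.groups + (("E",),), h2.trees + (leaf_tree("E"),), "IA")
        a2 = pc.simulate_forest(h2, wag, 60, seed=9)
        a3 = pc.simulate_forest(h3, wag, 60, seed=9)
        assert a2.restrict(["A", "B"]) == a3.restrict(["A", "B"])

    def test_cross_group_independence(self, wag):
        h = self._hyp()
        a = pc.simulate_forest(h, wag, 2000, seed=5)
        m1 = np.array([x == y for x, y in zip(a.rows[0], a.rows[1])])
        m2 = np.array([x == y for x, y in zip(a.rows[2], a.rows[3])])
        # permutation test on the match-indicator correlation
        rng = np.random.default_rng(0)
        obs = abs(np.corrcoef(m1, m2)[0, 1])
        null = [
            abs(np.corrcoef(m1, rng.permutation(m2))[0, 1])
            for _ in range(200)
        ]
        assert obs < np.quantile(null, 0.99)


class TestSimulateProfile:
    def test_point_mass_profile_identical_sequences(self):
        theta = np.zeros((5, 20))
        theta[:, 3] = 1.0
        a = pc.simulate_profile(pc.Profile(theta), 4, seed=1)
        assert set(a.rows) == {"DDDDD"}

    def test_column_frequency_recovery(self, rng):
        theta = rng.dirichlet(np.ones(20), size=2)
        a = pc.simulate_profile(pc.Profile(theta), 1000, seed=2)
        counts = pc.column_counts(a, 0).counts
        freq = counts / 1000
        se = np.sqrt(theta[0] * (1 - theta[0]) / 1000)
        assert (np.abs(freq - theta[0]) < 3 * se + 1e-9).all()

    def test_no_hierarchical_structure(self, rng):
        theta = rng.dirichlet(np.ones(20) * 0.3, size=400)
        a = pc.simulate_profile(pc.Profile(theta), 8, seed=4)

        def identity(i, j):
            return np.mean([c1 == c2 for c1, c2 in zip(a.rows[i], a.rows[j])])

        within = (identity(0, 1) + identity(2, 3)) / 2
        across = (identity(0, 2) + identity(1, 3)) / 2
        se = np.sqrt(0.25 / 400)
        assert abs(within - across) < 4 * se


class TestSimulateConflicting:
    def test_degenerate_weights_perfect_pairs(self):
        a = pc.simulate_conflicting(
            ("B", "E", "M", "P"), (1, 0, 0), within_identity=1.0, L=50, seed=1)
        assert a.rows[0] == a.rows[1]
        assert a.rows[2] == a.rows[3]

    def test_pairwise_identity_matches_closed_form(self):
        # within_identity 1, equal weights, uniform background:
        # P(match for any pair) = 1/3 + 2/3 * sum(pi^2)
        L = 20_000
        a = pc.simulate_conflicting(
            ("B", "E", "M", "P"), (1 / 3, 1 / 3, 1 / 3), 1.0, L, seed=2)
        expected = 1 / 3 + 2 / 3 * (20 * (1 / 20) ** 2)
        se = np.sqrt(expected * (1 - expected) / L)
        for i, j in [(0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3)]:
            ident = np.mean(
                [c1 == c2 for c1, c2 in zip(a.rows[i], a.rows[j])])
            assert abs(ident - expected) < 4 * se

    def test_invalid_inputs(self):
        with pytest.raises(Exception):
            pc.simulate_conflicting(("A", "B", "C"), L=10)
        with pytest.raises(ValueError):
            pc.simulate_conflicting(tuple("ABCD"), (0.5, 0.5, 0.5), L=10)
        with pytest.raises(ValueError):
            pc.simulate_conflicting(tuple("ABCD"), within_identity=0.0, L=10)

    def test_domain_profiles_give_distinct_compositions(self):
        a = pc.simulate_conflicting(
            tuple("BEMP"), L=2000, seed=3, within_identity=0.3,
            domain_concentration=0.05)
        from phyloca.treelik import empirical_frequencies

        f = [empirical_frequencies(a.restrict([n]), 0.0) for n in a.names]
        # sequences draw from different domain mixtures
        assert max(abs(f[0] - f[i]).sum() for i in (1, 2, 3)) > 0.2


class TestPermutationControl:
    def test_composition_preserved(self, wag):
        t = pc.read_newick("((A:.2,B:.2):.1,(C:.2,D:.2):.1);")
        a = pc.simulate_on_tree(t, wag, 120, seed=8)
        perm = pc.permutation_control(a, seed=1)
        for name in a.names:
            assert sorted(a.sequence(name)) == sorted(
                perm.sequence(name).replace("-", ""))

    def test_identical_inputs_decorrelate(self):
        s = "ACDEFGHIKLMNPQRSTVWY" * 4
        a = pc.Alignment(("x", "y"), (s, s))
        perm = pc.permutation_control(a, seed=2)
        r1 = perm.sequence("x").replace("-", "")
        r2 = perm.sequence("y").replace("-", "")
        assert r1 != r2
        m = pc.blosum62()
        realigned_score = pc.alignment_score(r1, r2, m)
        self_score = pc.alignment_score(s, s, m)
        assert realigned_score <= self_score


def test_progressive_align_identical_sequences_trivial():
    seqs = {"a": "ACDEFG", "b": "ACDEFG", "c": "ACDEFG"}
    a = progressive_align(seqs)
    assert a.length == 6 and len(set(a.rows)) == 1


class TestMakeFixture:
    def test_ca_tree_metadata_names_truth(self, tmp_path):
        spec = SimulationSpec("ca_tree", L=30, seed=1, params={
            "newick": "(A:0.1,B:0.1);", "matrix": "poisson"})
        meta = pc.make_fixture(spec, tmp_path / "f")
        assert meta["generating_model"] == "CA"
        assert (tmp_path / "f" / "alignment.fasta").exists()
        assert (tmp_path / "f" / "tree_0.nwk").exists()
        saved = json.loads((tmp_path / "f" / "metadata.json").read_text())
        assert saved["seed"] == 1

    def test_byte_identical_determinism(self, tmp_path):
        spec = SimulationSpec("conflicting", L=40, seed=2, params={})
        pc.make_fixture(spec, tmp_path / "a")
        pc.make_fixture(spec, tmp_path / "b")
        for name in ("alignment.fasta", "metadata.json"):
            assert (tmp_path / "a" / name).read_bytes() == (
                tmp_path / "b" / name).read_bytes()

    def test_profile_fixture_from_fitted_tree_alignment(self, tmp_path):
        spec = SimulationSpec("profile", L=25, seed=3, params={
            "base_newick": "((A:0.3,B:0.3):0.1,(C:0.3,D:0.3):0.1);",
            "matrix": "poisson", "n": 5})
        meta = pc.make_fixture(spec, tmp_path / "p")
        assert meta["generating_model"] == "profile"
        a = pc.read_fasta(tmp_path / "p" / "alignment.fasta")
        assert (a.n_sequences, a.length) == (5, 25)

    def test_unknown_scenario_rejected(self):
        with pytest.raises(ValueError):
            SimulationSpec("nope", L=10, seed=0)
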
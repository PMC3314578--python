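"""Synthetic-data generators and controls.

Four generators cover the scenarios the model-selection tests are meant to
discriminate: Markovian evolution along a tree (common ancestry, including
star trees), independent forests (each group evolved on its own tree with
its own random stream), the column-profile simulator (sequences drawn
independently from per-column categorical distributions — no phylogenetic
structure at all), and a conflicting-signal generator that builds four
highly similar sequences whose columns support incompatible pairings, so
no single tree fits them.

The permutation control bounds alignment-procedure bias: residues are
shuffled within each sequence (destroying all phylogenetic structure while
preserving composition) and the shuffles are re-aligned from scratch; any
remaining preference for common ancestry is an artifact of alignment.

All generators are deterministic given a seed; groups and sequences use
independent spawned substreams so enlarging a simulation does not perturb
the parts already generated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import HypothesisError
from .profilemodel import Profile, fit_profile
from .seqio import AMINO_ACIDS, Alignment, write_fasta
from .similarity import ScoringMatrix, alignment_score, blosum62
from .substmodels import SubstitutionModel
from .treelik import AncestryHypothesis, Tree, read_newick, star_tree, write_newick


def _rng(seed):
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def _draw_categorical(rng, probs, size):
    cdf = np.cumsum(probs)
    cdf[-1] = 1.0
    return np.searchsorted(cdf, rng.random(size), side="right")


# ---------------------------------------------------------------------------
# Tree / forest / profile simulators
# ---------------------------------------------------------------------------

def simulate_on_tree(t: Tree, m: SubstitutionModel, L: int, seed=0,
                     ) -> Alignment:
    """Evolve *L* sites along tree *t* under model *m*.

    Root states are drawn from the stationary distribution; each branch
    applies its transition matrix site by site.  A discrete-gamma rate
    category is drawn once per site and shared across the whole tree (the
    standard site-rate interpretation).
    """
    rng = _rng(seed)
    ncat = m.ncat
    cats = (_draw_categorical(rng, m.gamma.weights, L)
            if ncat > 1 else np.zeros(L, dtype=int))
    root_states = _draw_categorical(rng, m.pi, L)
    seqs: dict[str, np.ndarray] = {}

    def down(node, states):
        if node.is_leaf:
            seqs[node.label] = states
        for child in node.children:
            P = m.category_matrices(child.length)  # (ncat, 20, 20)
            cdf = np.cumsum(P, axis=2)
            cdf[..., -1] = 1.0
            rows = cdf[cats, states]               # (L, 20)
            child_states = (rows < rng.random(L)[:, None]).sum(axis=1)
            down(child, child_states)

    if t.root.is_leaf:
        seqs[t.root.label] = root_states
    else:
        down(t.root, root_states)
    aas = np.array(list(AMINO_ACIDS))
    names = t.leaf_names()
    return Alignment(tuple(names),
                     tuple("".join(aas[seqs[n]]) for n in names))


def simulate_forest(h: AncestryHypothesis, models, L: int, seed=0) -> Alignment:
    """Simulate each group independently and stack the rows.

    Each group gets its own spawned random stream, so the sequences of one
    group are unchanged if another group is added or altered.
    """
    models = (list(models) if isinstance(models, (list, tuple))
              else [models] * len(h.groups))
    if len(models) != len(h.groups):
        raise HypothesisError("one model per group required")
    streams = np.random.SeedSequence(seed).spawn(len(h.groups))
    names, rows = [], []
    for tree, model, ss in zip(h.trees, models, streams):
        sub = simulate_on_tree(tree, model, L, np.random.default_rng(ss))
        names.extend(sub.names)
        rows.extend(sub.rows)
    return Alignment(tuple(names), tuple(rows))


def simulate_profile(p: Profile, n: int, seed=0, names=None) -> Alignment:
    """Draw *n* sequences i.i.d. from the per-column distributions.

    Cell (i, site) ~ categorical(theta_site), independent across cells;
    one spawned stream per sequence.
    """
    if names is None:
        names = [f"S{i + 1}" for i in range(n)]
    if len(names) != n:
        raise ValueError("need one name per sequence")
    aas = np.array(list(AMINO_ACIDS))
    streams = np.random.SeedSequence(seed).spawn(n) if not isinstance(
        seed, np.random.Generator) else [seed] * n
    rows = []
    cdf = np.cumsum(p.theta, axis=1)
    cdf[:, -1] = 1.0
    for i in range(n):
        rng = np.random.default_rng(streams[i]) if not isinstance(
            streams[i], np.random.Generator) else streams[i]
        u = rng.random(p.length)
        states = (cdf < u[:, None]).sum(axis=1)
        rows.append("".join(aas[states]))
    return Alignment(tuple(names), tuple(rows))


#: The three ways four taxa can be split into two pairs.
PAIRINGS = (((0, 1), (2, 3)), ((0, 2), (1, 3)), ((0, 3), (1, 2)))


def simulate_conflicting(taxa, pairing_weights=(1 / 3, 1 / 3, 1 / 3),
                         within_identity: float = 1.0, L: int = 1000,
                         seed=0, pi=None,
                         domain_concentration: float | None = None,
                         domain_profiles=None) -> Alignment:
    """Four similar sequences with conflicting phylogenetic structure.

    Column by column, one of the three two-pair partitions of the four
    taxa is drawn with the given weights; within each pair the two
    residues are identical with probability *within_identity* and
    independent draws otherwise, and the two pairs are always independent.
    Every pairwise identity is elevated, but the support is split across
    incompatible pairings, so no single tree explains all columns.

    By default residues come from a single background distribution *pi*
    (uniform unless given).  Passing ``domain_concentration`` (or explicit
    ``domain_profiles`` of shape (3, 2, 20)) instead assigns each of the
    six (pairing, pair) combinations its own concentrated residue
    distribution — the "six distinct non-homologous domains" construction:
    each sequence then has an idiosyncratic composition, similarity is
    largely compositional, and independent-ancestry models with per-group
    frequencies fit far better than any single tree with shared
    frequencies.
    """
    taxa = list(taxa)
    if len(taxa) != 4:
        raise HypothesisError("the conflicting-signal generator needs 4 taxa")
    w = np.asarray(pairing_weights, dtype=float)
    if w.shape != (3,) or (w < 0).any() or not np.isclose(w.sum(), 1.0):
        raise ValueError("pairing weights must be 3 non-negatives summing to 1")
    if not 0 < within_identity <= 1:
        raise ValueError("within_identity must be in (0, 1]")
    rng = _rng(seed)
    if domain_profiles is not None:
        profiles = np.asarray(domain_profiles, dtype=float)
        if profiles.shape != (3, 2, 20):
            raise ValueError("domain_profiles must have shape (3, 2, 20)")
    elif domain_concentration is not None:
        # six mutually distinct domains: each concentrates on a private
        # block of residues (non-homologous domains differ in composition)
        perm = rng.permutation(20)
        profiles = np.empty((3, 2, 20))
        for d in range(6):
            alpha = np.full(20, domain_concentration)
            alpha[perm[3 * d:3 * d + 3]] += 1.0
            profiles[d // 2, d % 2] = rng.dirichlet(alpha)
    else:
        base = np.full(20, 1 / 20) if pi is None else np.asarray(pi, dtype=float)
        profiles = np.broadcast_to(base, (3, 2, 20))
    which = _draw_categorical(rng, w, L)
    cols = np.empty((L, 4), dtype=int)
    for s in range(L):
        for slot, pair in enumerate(PAIRINGS[which[s]]):
            p = profiles[which[s], slot]
            a = _draw_categorical(rng, p, 1)[0]
            b = a if rng.random() < within_identity else _draw_categorical(rng, p, 1)[0]
            cols[s, pair[0]] = a
            cols[s, pair[1]] = b
    aas = np.array(list(AMINO_ACIDS))
    return Alignment(tuple(taxa),
                     tuple("".join(aas[cols[:, i]]) for i in range(4)))


# ---------------------------------------------------------------------------
# Permutation control: shuffle within sequences, realign progressively
# ---------------------------------------------------------------------------

def _profile_align(block1, block2, matrix: ScoringMatrix):
    """Affine-gap global alignment of two aligned blocks (lists of rows).

    Columns are scored by the mean pairwise substitution score between the
    residues of the two blocks (gap rows contribute zero).
    """
    from .seqio import AA_INDEX

    def counts(block):
        L = len(block[0])
        c = np.zeros((L, 20))
        for row in block:
            for s, ch in enumerate(row):
                i = AA_INDEX.get(ch)
                if i is not None:
                    c[s, i] += 1
        return c

    C1, C2 = counts(block1), counts(block2)
    n1, n2 = len(block1), len(block2)
    colscore = (C1 @ matrix.scores @ C2.T) / (n1 * n2)
    Lx, Ly = colscore.shape
    go, ge = matrix.gap_open + matrix.gap_extend, matrix.gap_extend
    NEG = -1e18
    M = np.full((Lx + 1, Ly + 1), NEG)
    Ix = np.full((Lx + 1, Ly + 1), NEG)  # gap in block2 (consume x)
    Iy = np.full((Lx + 1, Ly + 1), NEG)  # gap in block1 (consume y)
    M[0, 0] = 0.0
    for i in range(1, Lx + 1):
        Ix[i, 0] = -go - (i - 1) * ge
    for j in range(1, Ly + 1):
        Iy[0, j] = -go - (j - 1) * ge
    for i in range(1, Lx + 1):
        for j in range(1, Ly + 1):
            M[i, j] = max(M[i - 1, j - 1], Ix[i - 1, j - 1],
                          Iy[i - 1, j - 1]) + colscore[i - 1, j - 1]
            Ix[i, j] = max(M[i - 1, j] - go, Ix[i - 1, j] - ge)
            Iy[i, j] = max(M[i, j - 1] - go, Iy[i, j - 1] - ge)
    # traceback
    i, j = Lx, Ly
    state = int(np.argmax([M[i, j], Ix[i, j], Iy[i, j]]))
    path = []
    while i > 0 or j > 0:
        if state == 0:
            path.append((i - 1, j - 1))
            prev = [M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1]]
            i, j = i - 1, j - 1
            state = int(np.argmax(prev))
        elif state == 1:
            path.append((i - 1, None))
            state = 0 if M[i - 1, j] - go >= Ix[i - 1, j] - ge else 1
            i -= 1
        else:
            path.append((None, j - 1))
            state = 0 if M[i, j - 1] - go >= Iy[i, j - 1] - ge else 2
            j -= 1
    path.reverse()
    merged1 = ["".join(row[i] if i is not None else "-" for i, _ in path)
               for row in block1]
    merged2 = ["".join(row[j] if j is not None else "-" for _, j in path)
               for row in block2]
    return merged1 + merged2


def progressive_align(seqs: dict[str, str], matrix: ScoringMatrix | None = None,
                      ) -> Alignment:
    """Progressive multiple alignment by pairwise-score-descending merges.

    Clusters are merged greedily: at each step the two clusters joined are
    those containing the highest-scoring remaining sequence pair
    (single linkage), ties broken by label order; blocks are merged with
    the affine-gap profile aligner.
    """
    matrix = matrix or blosum62()
    names = sorted(seqs)
    if len(names) < 2:
        raise ValueError("need at least 2 sequences")
    pair_score = {}
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pair_score[(a, b)] = alignment_score(seqs[a], seqs[b], matrix)
    clusters = {n: ([n], [seqs[n]]) for n in names}

    def find(name):
        for key, (members, _) in clusters.items():
            if name in members:
                return key
        raise KeyError(name)

    for (a, b), _ in sorted(pair_score.items(),
                            key=lambda kv: (-kv[1], kv[0])):
        ka, kb = find(a), find(b)
        if ka == kb:
            continue
        ma, ra = clusters.pop(ka)
        mb, rb = clusters.pop(kb)
        merged = _profile_align(ra, rb, matrix)
        clusters[min(ka, kb)] = (ma + mb, merged)
        if len(clusters) == 1:
            break
    members, rows = next(iter(clusters.values()))
    order = {n: i for i, n in enumerate(members)}
    return Alignment(tuple(members), tuple(rows))


def permutation_control(a: Alignment, matrix: ScoringMatrix | None = None,
                        seed=0) -> Alignment:
    """Shuffle residues within each sequence, then realign from scratch.

    Composition is preserved exactly (a permutation, not resampling); the
    result has no phylogenetic structure, so model-selection preference for
    common ancestry on the output bounds the bias introduced by the
    alignment procedure itself.
    """
    if a.n_sequences < 2:
        raise ValueError("need at least 2 sequences")
    rng = _rng(seed)
    shuffled = {}
    for name, row in zip(a.names, a.rows):
        residues = np.array([c for c in row if c != "-"])
        if residues.size == 0:
            raise ValueError(f"sequence {name!r} is all gaps")
        shuffled[name] = "".join(rng.permutation(residues))
    realigned = progressive_align(shuffled, matrix)
    # restore the input row order
    order = [realigned.names.index(n) for n in a.names]
    return Alignment(tuple(a.names), tuple(realigned.rows[i] for i in order))


# ---------------------------------------------------------------------------
# Fixture bundles
# ---------------------------------------------------------------------------

SCENARIOS = ("ca_tree", "ia_forest", "star", "profile", "conflicting")
_GENERATING_MODEL = {
    "ca_tree": "CA",
    "star": "CA",          # a star tree is a common-ancestry model
    "profile": "profile",
    "ia_forest": "IA",
    "conflicting": "IA",
}


@dataclass(frozen=True)
class SimulationSpec:
    """Complete description of one synthetic dataset."""

    scenario: str
    L: int
    seed: int
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}; "
                             f"choose from {SCENARIOS}")
        if self.L < 1:
            raise ValueError("L must be >= 1")


def _model_from_params(params) -> SubstitutionModel:
    from .substmodels import discrete_gamma, load_matrix

    matrix = load_matrix(params.get("matrix", "wag"))
    gamma = discrete_gamma(params.get("shape", 1.0), params.get("ncat", 1))
    return SubstitutionModel(matrix, gamma)


def realize(spec: SimulationSpec):
    """Generate the alignment (and trees, if any) for a spec."""
    p = spec.params
    if spec.scenario == "ca_tree":
        tree = read_newick(p["newick"])
        model = _model_from_params(p)
        return simulate_on_tree(tree, model, spec.L, spec.seed), [tree]
    if spec.scenario == "star":
        tree = star_tree(p["taxa"], p.get("branch_length", 0.3))
        model = _model_from_params(p)
        return simulate_on_tree(tree, model, spec.L, spec.seed), [tree]
    if spec.scenario == "ia_forest":
        trees = [read_newick(nwk) for nwk in p["newicks"]]
        groups = tuple(tuple(t.leaf_names()) for t in trees)
        h = AncestryHypothesis(groups, tuple(trees), "IA")
        model = _model_from_params(p)
        return simulate_forest(h, model, spec.L, spec.seed), trees
    if spec.scenario == "profile":
        if "base_newick" in p:
            # classic construction: fit the profile from a tree-simulated
            # alignment of real-looking homologs, then draw i.i.d. sequences
            base_tree = read_newick(p["base_newick"])
            model = _model_from_params(p)
            base = simulate_on_tree(base_tree, model, spec.L, spec.seed + 1)
            # plain observed column frequencies, as in the original recipe
            profile = fit_profile(base, pseudocount=p.get("pseudocount", 0.0))
        else:
            from .profilemodel import read_profile

            profile = read_profile(p["profile_path"])
        n = p.get("n", 12)
        return simulate_profile(profile, n, spec.seed, p.get("names")), []
    if spec.scenario == "conflicting":
        # defaults emulate the four-sequence counterexample: concentrated
        # per-domain compositions, moderate within-pair coupling
        return simulate_conflicting(
            p.get("taxa", ("B", "E", "M", "P")),
            p.get("pairing_weights", (0.4, 0.3, 0.3)),
            p.get("within_identity", 0.3),
            spec.L, spec.seed,
            domain_concentration=p.get("domain_concentration", 0.05)), []
    raise AssertionError(spec.scenario)


def make_fixture(spec: SimulationSpec, out_dir) -> dict:
    """Write alignment + trees + truth metadata for a spec; returns metadata.

    Output is byte-identical for identical specs.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    alignment, trees = realize(spec)
    write_fasta(alignment, out / "alignment.fasta")
    tree_files = []
    for i, tree in enumerate(trees):
        fname = f"tree_{i}.nwk"
        (out / fname).write_text(write_newick(tree) + "\n")
        tree_files.append(fname)
    meta = {
        "scenario": spec.scenario,
        "generating_model": _GENERATING_MODEL[spec.scenario],
        "seed": spec.seed,
        "L": spec.L,
        "n_sequences": alignment.n_sequences,
        "params": {k: v for k, v in sorted(spec.params.items())},
        "trees": tree_files,
    }
    (out / "metadata.json").write_text(
        json.dumps(meta, indent=2, sort_keys=True) + "\n")
    return meta
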
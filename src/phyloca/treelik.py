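"""Trees, forests and exact phylogenetic likelihoods.

The likelihood engine is Felsenstein's pruning algorithm with per-site,
per-node rescaling, a discrete-gamma rate mixture averaged per site, and
gaps/'X' treated as missing data (all-ones conditionals).  Trees are stored
rooted but evaluated under reversible models, so the likelihood is
invariant to the root placement; a root of degree two contributes a single
free branch length (the unrooted convention).

An :class:`AncestryHypothesis` partitions the taxa into one or more groups
with one tree per group.  A single group is a common-ancestry (CA) model;
two or more groups form an independent-ancestry (IA) "forest" whose
log-likelihood is the sum of the per-group log-likelihoods — statistical
independence of unrelated groups means the joint probability of the data
factorizes over groups.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize, minimize_scalar

from .errors import HypothesisError, NewickError
from .seqio import AMINO_ACIDS, Alignment, MISSING_CODE, all_column_counts
from .substmodels import SubstitutionModel, build_rate_matrix, discrete_gamma

BRANCH_MIN = 1e-8
BRANCH_MAX = 20.0
_DEFAULT_LENGTH = 0.1


class Node:
    """A tree node; ``length`` is the branch above it (root: ignored)."""

    __slots__ = ("label", "length", "children")

    def __init__(self, label=None, length=0.0, children=None):
        self.label = label
        self.length = float(length)
        self.children = list(children) if children else []

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Tree:
    root: Node

    def __post_init__(self):
        names = self.leaf_names()
        if len(set(names)) != len(names):
            raise NewickError(f"duplicate leaf labels in tree: {sorted(names)}")
        for node in self.postorder():
            if node is not self.root and (
                not np.isfinite(node.length) or node.length < 0
            ):
                raise NewickError(f"invalid branch length {node.length}")

    def postorder(self):
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return out[::-1]

    def leaves(self):
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self):
        return [n.label for n in self.leaves()]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves())

    @property
    def is_star(self) -> bool:
        """One internal node joined directly to every leaf."""
        return (
            not self.root.is_leaf
            and all(c.is_leaf for c in self.root.children)
            and len(self.root.children) >= 3
        )

    def copy(self) -> "Tree":
        def rec(n):
            return Node(n.label, n.length, [rec(c) for c in n.children])

        return Tree(rec(self.root))

    def total_length(self) -> float:
        return sum(n.length for n in self.postorder() if n is not self.root)


def star_tree(taxa, branch_lengths=0.1) -> Tree:
    """Star phylogeny: one internal node joined to every leaf."""
    taxa = list(taxa)
    if len(taxa) < 2:
        raise HypothesisError("a star tree needs at least 2 taxa")
    if np.isscalar(branch_lengths):
        branch_lengths = [branch_lengths] * len(taxa)
    if len(branch_lengths) != len(taxa):
        raise HypothesisError("one branch length per taxon required")
    return Tree(Node(children=[Node(t, b) for t, b in zip(taxa, branch_lengths)]))


def leaf_tree(taxon: str) -> Tree:
    """Degenerate one-taxon 'tree' (stationary distribution only)."""
    return Tree(Node(taxon))


# ---------------------------------------------------------------------------
# Newick I/O (parsing via dendropy)
# ---------------------------------------------------------------------------

def read_newick(text: str) -> Tree:
    try:
        dt = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:
        raise NewickError(f"cannot parse Newick: {exc}") from None

    def convert(dnode):
        label = dnode.taxon.label if dnode.taxon is not None else None
        length = dnode.edge.length if dnode.edge.length is not None else _DEFAULT_LENGTH
        node = Node(label, max(0.0, length), [convert(c) for c in dnode.child_nodes()])
        return node

    root = convert(dt.seed_node)
    root.length = 0.0
    return Tree(root)


def write_newick(t: Tree) -> str:
    def rec(node):
        if node.is_leaf:
            return f"{node.label}:{node.length:.10g}"
        inner = ",".join(rec(c) for c in node.children)
        if node is t.root:
            return f"({inner})"
        return f"({inner}):{node.length:.10g}"

    return rec(t.root) + ";"


def read_newick_file(path) -> Tree:
    with open(path) as fh:
        return read_newick(fh.read())


# ---------------------------------------------------------------------------
# Pruning likelihood
# ---------------------------------------------------------------------------

def _leaf_partials(a: Alignment, ncat: int) -> dict[str, np.ndarray]:
    """(L, ncat, 20) conditional arrays per taxon; missing data -> ones."""
    enc = a.encoded()
    out = {}
    eye = np.eye(20)
    for i, name in enumerate(a.names):
        codes = enc[i]
        part = np.ones((a.length, 20))
        obs = codes != MISSING_CODE
        part[obs] = eye[codes[obs]]
        out[name] = np.broadcast_to(part[:, None, :], (a.length, ncat, 20)).copy()
    return out


class PruningEngine:
    """Incremental pruning likelihood for repeated branch-length updates.

    Caches each node's conditional partial (L, ncat, 20), the "message"
    sent through its branch (P(t) applied to the partial), and the
    per-node rescaling applied for numerical stability.  Changing one
    branch length only recomputes that edge's message and the partials on
    the path to the root, which makes coordinate-wise optimization and
    MCMC over branch lengths cheap on larger trees.

    The engine owns a private copy of the tree; read the fitted lengths
    back through :attr:`tree`.
    """

    def __init__(self, t: Tree, a: Alignment, m: SubstitutionModel,
                 copy: bool = True):
        missing = set(t.leaf_names()) - set(a.names)
        if missing:
            raise HypothesisError(
                f"tree leaves without sequences: {sorted(missing)}"
            )
        self.tree = t.copy() if copy else t
        self.alignment = a
        self.L = a.length
        self.model = m
        self._parent = {}
        for node in self.tree.postorder():
            for child in node.children:
                self._parent[id(child)] = node
        self._leaf_parts = None
        self._partial = {}
        self._message = {}
        self._scale = {}
        self.set_model(m)

    def set_model(self, m: SubstitutionModel) -> None:
        """Swap the substitution model and refresh everything."""
        rebuild_leaves = (
            self._leaf_parts is None or m.ncat != self.model.ncat
        )
        self.model = m
        if rebuild_leaves:
            self._leaf_parts = _leaf_partials(
                self.alignment.restrict(self.tree.leaf_names()), m.ncat
            )
        for node in self.tree.postorder():
            self._refresh_partial(node)
            if node is not self.tree.root:
                self._refresh_message(node)

    def _refresh_partial(self, node) -> None:
        if node.is_leaf:
            self._partial[id(node)] = self._leaf_parts[node.label]
            self._scale[id(node)] = 0.0
            return
        part = self._message[id(node.children[0])].copy()
        for child in node.children[1:]:
            part *= self._message[id(child)]
        scale = part.max(axis=(1, 2))
        np.clip(scale, 1e-300, None, out=scale)
        part /= scale[:, None, None]
        self._partial[id(node)] = part
        self._scale[id(node)] = np.log(scale).sum()

    def _refresh_message(self, node) -> None:
        P = self.model.category_matrices(node.length)
        self._message[id(node)] = np.einsum(
            "cab,scb->sca", P, self._partial[id(node)]
        )

    def set_length(self, node, t: float) -> None:
        """Update one branch length and propagate to the root."""
        node.length = float(t)
        self._refresh_message(node)
        cur = self._parent[id(node)]
        while cur is not None:
            self._refresh_partial(cur)
            if cur is self.tree.root:
                break
            self._refresh_message(cur)
            cur = self._parent[id(cur)]

    def loglik(self) -> float:
        m = self.model
        root = self.tree.root
        part = self._partial[id(root)]
        site = np.einsum("a,sca,c->s", m.pi, part, m.gamma.weights)
        if (site <= 0).any():
            raise FloatingPointError("non-finite site likelihood encountered")
        total = float(np.log(site).sum())
        for node in self.tree.postorder():
            if not node.is_leaf:
                total += self._scale[id(node)]
        if not np.isfinite(total):
            raise FloatingPointError("non-finite log-likelihood")
        return total


def loglik(t: Tree, a: Alignment, m: SubstitutionModel) -> float:
    """Exact log-likelihood of alignment *a* on tree *t* under model *m*.

    Felsenstein pruning with per-node rescaling; sites independent,
    per-site likelihoods averaged over the discrete-gamma categories,
    gaps/'X' as missing data.  A single-leaf "tree" reduces to the
    stationary term sum(log pi(residue)).
    """
    if t.root.is_leaf:
        # no branches: stationary distribution only
        enc = a.restrict([t.root.label]).encoded()[0]
        obs = enc != MISSING_CODE
        return float(np.log(m.pi[enc[obs]]).sum())
    return PruningEngine(t, a, m).loglik()


# ---------------------------------------------------------------------------
# Free branch-length parameters (unrooted convention)
# ---------------------------------------------------------------------------

def free_edge_groups(t: Tree) -> list[list[Node]]:
    """Independent branch-length parameters of a tree.

    All non-root nodes carry one branch each, except that a degree-two root
    joins its two child branches into a single unrooted edge (the value is
    carried on the first child; the second is pinned at zero).
    """
    groups = []
    if len(t.root.children) == 2:
        a, b = t.root.children
        a.length += b.length
        b.length = 0.0
        groups.append([a, b])
        rest = [n for n in t.postorder() if n not in (t.root, a, b)]
    else:
        rest = [n for n in t.postorder() if n is not t.root]
    groups.extend([n] for n in rest)
    return groups


def get_group_length(group) -> float:
    return group[0].length


def set_group_length(group, value: float) -> None:
    group[0].length = float(value)
    for n in group[1:]:
        n.length = 0.0


# ---------------------------------------------------------------------------
# Hypotheses
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AncestryHypothesis:
    """A partition of the taxa with one tree per group.

    One group = common ancestry; two or more groups = independent ancestry.
    """

    groups: tuple[tuple[str, ...], ...]
    trees: tuple[Tree, ...]
    label: str = ""

    def __post_init__(self):
        if len(self.groups) != len(self.trees):
            raise HypothesisError("one tree per group required")
        seen: set[str] = set()
        for group, tree in zip(self.groups, self.trees):
            gset = set(group)
            if len(gset) != len(group):
                raise HypothesisError(f"duplicate taxa inside group {group}")
            if seen & gset:
                raise HypothesisError(f"overlapping groups at {sorted(seen & gset)}")
            seen |= gset
            if set(tree.leaf_names()) != gset:
                raise HypothesisError(
                    f"tree leaves {sorted(tree.leaf_names())} do not match "
                    f"group {sorted(gset)}"
                )

    @property
    def taxa(self) -> set[str]:
        return {t for g in self.groups for t in g}

    @property
    def is_common_ancestry(self) -> bool:
        return len(self.groups) == 1

    @classmethod
    def common_ancestry(cls, tree: Tree, label: str = "CA") -> "AncestryHypothesis":
        return cls((tuple(tree.leaf_names()),), (tree,), label)


def parse_partition(text: str, taxa) -> tuple[tuple[str, ...], ...]:
    """Parse a partition string like ``"BE+MP"`` or ``"Human,Chimp+Yeast"``.

    Groups are separated by ``+``.  Within a group, taxa are separated by
    commas; if every taxon label is a single character, a group may also be
    written as a run of letters (``"BEMP"``).
    """
    taxa = list(taxa)
    single = all(len(t) == 1 for t in taxa)
    groups = []
    for chunk in text.split("+"):
        chunk = chunk.strip()
        if not chunk:
            raise HypothesisError(f"empty group in partition {text!r}")
        if "," in chunk or not single:
            members = tuple(s.strip() for s in chunk.split(","))
        else:
            members = tuple(chunk)
        groups.append(members)
    flat = [t for g in groups for t in g]
    if sorted(flat) != sorted(taxa):
        raise HypothesisError(
            f"partition {text!r} does not cover taxa {sorted(taxa)} exactly"
        )
    return tuple(groups)


def forest_loglik(h: AncestryHypothesis, a: Alignment, m) -> float:
    """Sum of per-group log-likelihoods (Eq. of independence of groups).

    *m* may be a single model shared by all groups or a sequence with one
    model per group (each independent lineage has its own parameters).
    """
    if h.taxa != set(a.names):
        raise HypothesisError(
            "hypothesis taxa do not cover the alignment "
            f"(missing {sorted(set(a.names) ^ h.taxa)})"
        )
    models = list(m) if isinstance(m, (list, tuple)) else [m] * len(h.groups)
    if len(models) != len(h.groups):
        raise HypothesisError("one model per group required")
    total = 0.0
    for group, tree, model in zip(h.groups, h.trees, models):
        total += loglik(tree, a.restrict(group), model)
    return total


def count_parameters(h: AncestryHypothesis, convention: str = "unrooted") -> int:
    """Free-parameter count K of a tree hypothesis.

    Per group of size s: branch lengths of the unrooted tree (2s-3 for
    s >= 2, zero for a singleton), 19 free equilibrium frequencies, and one
    gamma shape (not identifiable and not counted for singletons).  The
    ``table2_compat`` convention differs only in charging two-taxon groups
    two branch lengths instead of one.
    """
    if convention not in ("unrooted", "table2_compat"):
        raise HypothesisError(f"unknown convention {convention!r}")
    K = 0
    for group in h.groups:
        s = len(group)
        if s == 1:
            branches = 0
        elif s == 2:
            branches = 2 if convention == "table2_compat" else 1
        else:
            branches = 2 * s - 3
        K += branches + 19 + (1 if s > 1 else 0)
    return K


# ---------------------------------------------------------------------------
# Branch-length (and shape/frequency) optimization
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    tree: Tree
    model: SubstitutionModel
    loglik: float
    converged: bool
    rounds: int


def empirical_frequencies(a: Alignment, pseudocount: float = 0.5) -> np.ndarray:
    """Observed residue frequencies with a small regularizing pseudocount."""
    counts = all_column_counts(a).sum(axis=0).astype(float) + pseudocount
    return counts / counts.sum()


def optimize_branch_lengths(
    t: Tree,
    a: Alignment,
    m: SubstitutionModel,
    *,
    optimize_shape: bool = False,
    optimize_frequencies: bool = False,
    tol: float = 1e-6,
    max_rounds: int = 200,
    bounds: tuple[float, float] = (BRANCH_MIN, BRANCH_MAX),
) -> FitResult:
    """Maximize lnL by coordinate ascent over free branch lengths.

    One-dimensional bounded optimization per branch (Brent), optionally
    interleaved with gamma-shape and frequency updates, until the round
    improvement drops below *tol*.  Single-leaf trees have nothing to
    optimize and return the stationary log-likelihood directly.
    """
    model = m
    if t.root.is_leaf:
        return FitResult(t.copy(), model, loglik(t, a, model), True, 0)
    tree = t.copy()
    groups = free_edge_groups(tree)
    engine = PruningEngine(tree, a, model, copy=False)

    def set_group(group, x):
        engine.set_length(group[0], x)
        for n in group[1:]:
            engine.set_length(n, 0.0)

    for group in groups:
        set_group(group, get_group_length(group))
    best = engine.loglik()
    converged = False
    rounds = 0
    for rounds in range(1, max_rounds + 1):
        start = best
        for group in groups:
            orig = get_group_length(group)

            def neg(x, _g=group):
                set_group(_g, x)
                return -engine.loglik()

            res = minimize_scalar(
                neg, bounds=bounds, method="bounded",
                options={"xatol": 1e-8},
            )
            if -res.fun >= best:
                set_group(group, float(res.x))
                best = -res.fun
            else:
                set_group(group, orig)
        if optimize_shape and model.gamma.ncat > 1:
            def neg_shape(logs):
                engine.set_model(model.with_shape(float(np.exp(logs))))
                return -engine.loglik()

            res = minimize_scalar(
                neg_shape, bounds=(np.log(0.05), np.log(50.0)), method="bounded",
                options={"xatol": 1e-6},
            )
            if -res.fun >= best:
                model = model.with_shape(float(np.exp(res.x)))
                best = -res.fun
            engine.set_model(model)
        if optimize_frequencies:
            model, best = _optimize_frequencies(engine, model, best)
        if best - start < tol:
            converged = True
            break
    return FitResult(tree, model, best, converged, rounds)


def _optimize_frequencies(engine, model, best):
    """One L-BFGS pass over softmax-parametrized equilibrium frequencies."""
    x0 = np.log(model.pi / model.pi[-1])[:-1]

    def unpack(x):
        z = np.concatenate([x, [0.0]])
        e = np.exp(z - z.max())
        return e / e.sum()

    def neg(x):
        pi = np.clip(unpack(x), 1e-8, None)
        engine.set_model(model.with_frequencies(pi))
        return -engine.loglik()

    res = minimize(neg, x0, method="L-BFGS-B", options={"maxiter": 25})
    if -res.fun > best:
        model = model.with_frequencies(np.clip(unpack(res.x), 1e-8, None))
        best = -res.fun
    engine.set_model(model)
    return model, best


def fit_hypothesis(
    h: AncestryHypothesis,
    a: Alignment,
    base_model: SubstitutionModel,
    *,
    frequencies: str = "empirical",
    optimize_shape: bool = False,
    **opt_kwargs,
) -> tuple[AncestryHypothesis, list[SubstitutionModel], float]:
    """ML-fit every group of a hypothesis independently.

    Each group receives its own frequency vector (``"empirical"`` from its
    sub-alignment, ``"ml"`` optimized, or ``"fixed"`` from the base model)
    and, when requested, its own gamma shape.  Returns the fitted
    hypothesis, per-group models, and the total log-likelihood.
    """
    if frequencies not in ("fixed", "empirical", "ml"):
        raise HypothesisError(f"unknown frequency mode {frequencies!r}")
    fitted_trees, models, total = [], [], 0.0
    for group, tree in zip(h.groups, h.trees):
        sub = a.restrict(group)
        model = base_model
        if frequencies == "empirical":
            model = model.with_frequencies(empirical_frequencies(sub))
        res = optimize_branch_lengths(
            tree, sub, model,
            optimize_shape=optimize_shape,
            optimize_frequencies=(frequencies == "ml"),
            **opt_kwargs,
        )
        fitted_trees.append(res.tree)
        models.append(res.model)
        total += res.loglik
    fitted = AncestryHypothesis(h.groups, tuple(fitted_trees), h.label)
    return fitted, models, total


# ---------------------------------------------------------------------------
# Topologies
# ---------------------------------------------------------------------------

def enumerate_topologies(taxa, branch_length: float = 0.1) -> list[Tree]:
    """All unrooted binary topologies for up to seven taxa.

    Trees are built by the standard stepwise-addition enumeration: each new
    leaf is attached to every edge of every existing topology (3, 15, 105,
    945 trees for 4..7 taxa).
    """
    taxa = list(taxa)
    if len(taxa) < 2:
        raise HypothesisError("need at least 2 taxa")
    if len(taxa) > 7:
        raise HypothesisError("exhaustive enumeration limited to 7 taxa")
    if len(taxa) == 2:
        return [Tree(Node(children=[Node(taxa[0], branch_length),
                                    Node(taxa[1], branch_length)]))]

    def base():
        return Node(children=[Node(t, branch_length) for t in taxa[:3]])

    partial = [base()]
    for new_taxon in taxa[3:]:
        grown = []
        for root in partial:
            edges = _edge_count(root)
            for k in range(edges):
                clone = _clone(root)
                _attach_at(clone, [k], new_taxon, branch_length)
                grown.append(clone)
        partial = grown
    return [Tree(r) for r in partial]


def _edge_count(root) -> int:
    return sum(1 for _ in _iter_edges(root))


def _iter_edges(root):
    stack = list(root.children)
    while stack:
        node = stack.pop()
        yield node
        stack.extend(node.children)


def _clone(node):
    return Node(node.label, node.length, [_clone(c) for c in node.children])


def _attach_at(root, counter, new_taxon, branch_length):
    """Split the counter[0]-th edge of *root* and hang the new leaf there."""
    for parent in _preorder_parents(root):
        for i, child in enumerate(parent.children):
            if counter[0] == 0:
                mid = Node(None, child.length / 2.0)
                child.length = child.length / 2.0
                mid.children = [child, Node(new_taxon, branch_length)]
                parent.children[i] = mid
                counter[0] = -1
                return
            counter[0] -= 1
    raise AssertionError("edge index out of range")


def _preorder_parents(root):
    stack = [root]
    while stack:
        node = stack.pop()
        if node.children:
            yield node
            stack.extend(node.children)


def nj_topology(a: Alignment, min_length: float = 1e-6) -> Tree:
    """Neighbor-joining guide topology from pairwise p-distances."""
    from skbio import DistanceMatrix
    from skbio.tree import nj

    enc = a.encoded()
    n = a.n_sequences
    d = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        both = (enc[i] != MISSING_CODE) & (enc[j] != MISSING_CODE)
        tot = both.sum()
        diff = (enc[i][both] != enc[j][both]).sum()
        d[i, j] = d[j, i] = diff / tot if tot else 0.0
    dm = DistanceMatrix(d, ids=list(a.names))
    newick = str(nj(dm)).strip()
    tree = read_newick(newick)
    for node in tree.postorder():
        if node is not tree.root:
            node.length = max(node.length, min_length)
    return tree
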
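import numpy as np
import pytest

import phyloca as pc
from phyloca.seqio import MISSING_CODE


@pytest.fixture(scope="session")
def poisson():
    return pc.poisson_model()


@pytest.fixture(scope="session")
def wag():
    return pc.SubstitutionModel(pc.load_matrix("wag"))


@pytest.fixture(scope="session")
def wag_gamma():
    return pc.SubstitutionModel(pc.load_matrix("wag"), pc.discrete_gamma(0.7, 3))


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture()
def small_alignment():
    return pc.Alignment(("A", "B", "C", "D"), ("ACDE", "AC-E", "GXDE", "ACDF"))


def brute_force_loglik(t, a, m):
    """Exhaustive-enumeration likelihood: sum over every assignment of
    states to internal nodes.  Independent oracle for the pruning engine;
    feasible for <= 5 leaves and a handful of sites."""
    enc = a.restrict(t.leaf_names()).encoded()
    row = {n: i for i, n in enumerate(a.restrict(t.leaf_names()).names)}
    nodes = t.postorder()
    internal = [n for n in nodes if not n.is_leaf]
    total = 0.0
    for s in range(a.length):
        site_lik = 0.0
        for w, r in zip(m.gamma.weights, m.gamma.rates):
            P = {
                id(n): pc.transition_probabilities(m.rates, n.length * r)
                for n in nodes if n is not t.root
            }
            site_cat = 0.0
            for assign in np.ndindex(*(20,) * len(internal)):
                states = {id(n): st for n, st in zip(internal, assign)}
                p = m.pi[states[id(t.root)]]
                for n in nodes:
                    if n is t.root:
                        continue
                    parent_state = states[id(_parent_of(t, n))]
                    if n.is_leaf:
                        code = enc[row[n.label], s]
                        if code != MISSING_CODE:
                            p *= P[id(n)][parent_state, code]
                    else:
                        p *= P[id(n)][parent_state, states[id(n)]]
                site_cat += p
            site_lik += w * site_cat
        total += np.log(site_lik)
    return float(total)


def _parent_of(t, node):
    for n in t.postorder():
        if node in n.children:
            return n
    raise AssertionError("node not in tree")
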
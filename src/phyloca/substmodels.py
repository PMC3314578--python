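"""Amino-acid substitution processes.

A reversible rate matrix is assembled from symmetric exchangeabilities
``s_ab`` and equilibrium frequencies ``pi`` as ``Q_ab = s_ab * pi_b``
(a != b), with the diagonal set so rows sum to zero and the whole matrix
rescaled so that the expected number of substitutions per unit branch
length is one (``-sum_a pi_a Q_aa = 1``).  Transition probabilities are
computed from the symmetrized eigendecomposition of Q, which is exact for
reversible models and lets the likelihood engine evaluate ``P(t)`` for
many branch lengths cheaply.

Among-site rate heterogeneity uses the discrete-gamma approximation with
equal-weight categories and mean category rates (Yang's convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from scipy.special import gammainc
from scipy.stats import gamma as gamma_dist

from .errors import MatrixFormatError, ModelError

N_STATES = 20


@dataclass(frozen=True)
class RateMatrix:
    """Normalized reversible 20x20 generator with its spectral decomposition."""

    exchangeabilities: np.ndarray = field(repr=False)
    pi: np.ndarray = field(repr=False)
    Q: np.ndarray = field(repr=False, default=None)
    # eigendecomposition of the symmetrized generator, cached for P(t)
    _eigvals: np.ndarray = field(repr=False, default=None)
    _right: np.ndarray = field(repr=False, default=None)
    _left: np.ndarray = field(repr=False, default=None)

    def transition_probabilities(self, t: float) -> np.ndarray:
        return transition_probabilities(self, t)


def build_rate_matrix(exchangeabilities, pi) -> RateMatrix:
    """Assemble and normalize a reversible rate matrix.

    Raises :class:`ModelError` on asymmetric exchangeabilities or invalid
    frequencies.
    """
    s = np.asarray(exchangeabilities, dtype=float)
    pi = np.asarray(pi, dtype=float)
    if s.shape != (N_STATES, N_STATES):
        raise ModelError(f"exchangeabilities must be 20x20, got {s.shape}")
    if not np.allclose(s, s.T, atol=1e-10):
        raise ModelError("exchangeability matrix must be symmetric")
    if (s < 0).any():
        raise ModelError("exchangeabilities must be non-negative")
    if pi.shape != (N_STATES,) or (pi <= 0).any():
        raise ModelError("frequencies must be 20 positive values")
    pi = pi / pi.sum()

    Q = s * pi[None, :]
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    if rate <= 0:
        raise ModelError("degenerate rate matrix (zero total rate)")
    Q = Q / rate

    # B = D^{1/2} Q D^{-1/2} is symmetric for reversible Q
    sq = np.sqrt(pi)
    B = (Q * sq[:, None]) / sq[None, :]
    B = (B + B.T) / 2.0
    eigvals, V = np.linalg.eigh(B)
    right = V / sq[:, None]          # columns: right eigenvectors of Q
    left = V * sq[:, None]           # columns: left eigenvectors (inverse^T)

    obj = RateMatrix(exchangeabilities=s, pi=pi, Q=Q)
    object.__setattr__(obj, "_eigvals", eigvals)
    object.__setattr__(obj, "_right", right)
    object.__setattr__(obj, "_left", left)
    return obj


def transition_probabilities(m: RateMatrix, t: float) -> np.ndarray:
    """P(t) = exp(Qt); rows sum to 1, entries clamped at 0."""
    if t < 0:
        raise ModelError(f"branch length must be >= 0, got {t}")
    ex = np.exp(m._eigvals * t)
    P = (m._right * ex[None, :]) @ m._left.T
    np.clip(P, 0.0, None, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


# ---------------------------------------------------------------------------
# PAML-style .dat files: 19 lower-triangular exchangeability rows, then 20
# equilibrium frequencies.
# ---------------------------------------------------------------------------

def read_paml_matrix(path):
    """Read a PAML-layout .dat file -> (exchangeabilities, pi)."""
    tokens: list[float] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            for tok in line.split():
                try:
                    tokens.append(float(tok))
                except ValueError:
                    raise MatrixFormatError(
                        f"{path}:{lineno}: non-numeric token {tok!r}"
                    ) from None
    need = 190 + 20
    if len(tokens) != need:
        raise MatrixFormatError(
            f"{path}: expected {need} numbers (190 exchangeabilities + "
            f"20 frequencies), found {len(tokens)}"
        )
    s = np.zeros((N_STATES, N_STATES))
    k = 0
    for i in range(1, N_STATES):
        for j in range(i):
            s[i, j] = s[j, i] = tokens[k]
            k += 1
    pi = np.array(tokens[190:])
    pi = pi / pi.sum()
    return s, pi


def write_paml_matrix(exchangeabilities, pi, path) -> None:
    s = np.asarray(exchangeabilities, dtype=float)
    with open(path, "w") as fh:
        for i in range(1, N_STATES):
            fh.write(" ".join(f"{s[i, j]:.6f}" for j in range(i)) + "\n")
        fh.write("\n")
        fh.write(" ".join(f"{p:.6f}" for p in np.asarray(pi)) + "\n")


def load_matrix(name: str) -> RateMatrix:
    """Load a bundled empirical matrix: ``wag``, ``lg``, or ``poisson``."""
    name = name.lower()
    if name == "poisson":
        s = np.ones((N_STATES, N_STATES))
        np.fill_diagonal(s, 0.0)
        return build_rate_matrix(s, np.full(N_STATES, 1.0 / N_STATES))
    ref = resources.files("phyloca.data") / f"{name}.dat"
    if not ref.is_file():
        raise ModelError(f"no bundled matrix named {name!r} (wag, lg, poisson)")
    with resources.as_file(ref) as p:
        s, pi = read_paml_matrix(p)
    return build_rate_matrix(s, pi)


# ---------------------------------------------------------------------------
# Discrete gamma rates
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GammaRates:
    shape: float
    ncat: int
    rates: np.ndarray = field(repr=False)
    weights: np.ndarray = field(repr=False)


def discrete_gamma(shape: float, ncat: int) -> GammaRates:
    """Equal-weight discrete gamma categories with mean category rates.

    Category boundaries are the ``i/ncat`` quantiles of Gamma(shape, 1/shape);
    the category rate is the conditional mean of the gamma density on its
    segment, renormalized so the mixture mean is exactly 1.
    """
    if shape <= 0:
        raise ModelError(f"gamma shape must be > 0, got {shape}")
    if ncat < 1:
        raise ModelError(f"ncat must be >= 1, got {ncat}")
    if ncat == 1:
        return GammaRates(shape, 1, np.array([1.0]), np.array([1.0]))
    probs = np.arange(1, ncat) / ncat
    cuts = gamma_dist.ppf(probs, a=shape, scale=1.0 / shape)
    bounds = np.concatenate([[0.0], cuts, [np.inf]])
    # E[X; a<X<b] for Gamma(shape, 1/shape) via the regularized incomplete
    # gamma of shape+1 (mean of the full distribution is 1)
    upper = np.where(np.isinf(bounds[1:]), 1.0, gammainc(shape + 1, shape * bounds[1:]))
    lower = gammainc(shape + 1, shape * bounds[:-1])
    rates = ncat * (upper - lower)
    rates = rates / rates.mean()
    weights = np.full(ncat, 1.0 / ncat)
    return GammaRates(shape, ncat, rates, weights)


@dataclass(frozen=True)
class SubstitutionModel:
    """A rate matrix plus optional discrete-gamma rate heterogeneity."""

    rates: RateMatrix
    gamma: GammaRates = None

    def __post_init__(self):
        if self.gamma is None:
            object.__setattr__(self, "gamma", discrete_gamma(1.0, 1))

    @property
    def pi(self) -> np.ndarray:
        return self.rates.pi

    @property
    def ncat(self) -> int:
        return self.gamma.ncat

    def with_frequencies(self, pi) -> "SubstitutionModel":
        return SubstitutionModel(
            build_rate_matrix(self.rates.exchangeabilities, pi), self.gamma
        )

    def with_shape(self, shape: float) -> "SubstitutionModel":
        return SubstitutionModel(self.rates, discrete_gamma(shape, self.gamma.ncat))

    def category_matrices(self, t: float) -> np.ndarray:
        """(ncat, 20, 20) transition matrices for one branch of length t."""
        return np.stack(
            [transition_probabilities(self.rates, t * r) for r in self.gamma.rates]
        )


def poisson_model(ncat: int = 1, shape: float = 1.0) -> SubstitutionModel:
    return SubstitutionModel(load_matrix("poisson"), discrete_gamma(shape, ncat))


def wag_model(ncat: int = 4, shape: float = 1.0) -> SubstitutionModel:
    return SubstitutionModel(load_matrix("wag"), discrete_gamma(shape, ncat))
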
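"""Head-to-head model comparison.

Maximum-likelihood fits are compared by log-likelihood ratios and by the
half-AIC convention ``(-lnL + K)`` differences; Bayesian fits by ln Bayes
factors from marginal likelihoods.  Marginal likelihoods of tree models
are estimated by stepping-stone sampling over branch lengths (plus gamma
shape and equilibrium frequencies when requested); the profile model's
marginal is analytic and enters the comparison with zero Monte-Carlo
error.  Forests (independent-ancestry hypotheses) factorize: the joint
marginal is the sum of per-group marginals because the groups share no
parameters and their priors are independent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .errors import HypothesisError
from .profilemodel import DirichletPrior, profile_marginal_loglik
from .seqio import Alignment
from .substmodels import SubstitutionModel
from .treelik import (
    BRANCH_MAX,
    BRANCH_MIN,
    AncestryHypothesis,
    Tree,
    free_edge_groups,
    get_group_length,
    loglik,
    set_group_length,
)

MAX_LOGLIK = "max_loglik"
LN_MARGINAL = "ln_marginal"


@dataclass(frozen=True)
class ModelScore:
    """One model's score: a maximized lnL or a ln marginal likelihood."""

    label: str
    score_type: str
    value: float
    K: int | None = None
    sem: float | None = None
    family: str = "tree"

    def __post_init__(self):
        if self.score_type not in (MAX_LOGLIK, LN_MARGINAL):
            raise ValueError(f"unknown score type {self.score_type!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"score must be finite, got {self.value}")
        if self.sem is not None and self.sem < 0:
            raise ValueError("sem must be >= 0")


def _require(score_type, *scores):
    for s in scores:
        if s.score_type != score_type:
            raise ValueError(
                f"expected {score_type} scores, got {s.score_type} for {s.label!r}"
            )


def llr(ca: ModelScore, other: ModelScore) -> float:
    """lnL(ca) - lnL(other); negative means *other* fits better."""
    _require(MAX_LOGLIK, ca, other)
    return ca.value - other.value


_PROFILE_AIC_WARNING = (
    "AIC/LLR comparisons involving the profile model are unreliable: the "
    "model has 19 free parameters per column, so the data-to-parameter "
    "ratio is far below the asymptotic regime these criteria assume. "
    "Use Bayes factors instead."
)


def delta_aic(ca: ModelScore, other: ModelScore, convention: str = "table2") -> float:
    """Penalized fit difference of *other* relative to *ca*.

    ``table2`` convention: (-lnL + K)_other - (-lnL + K)_ca (half the
    standard AIC difference); ``standard``: twice that.  Negative values
    favour *other*.
    """
    _require(MAX_LOGLIK, ca, other)
    if ca.K is None or other.K is None:
        raise ValueError("both scores must carry a parameter count K")
    if "profile" in (ca.family, other.family):
        warnings.warn(_PROFILE_AIC_WARNING, UserWarning, stacklevel=2)
    half = (-other.value + other.K) - (-ca.value + ca.K)
    if convention == "table2":
        return half
    if convention == "standard":
        return 2.0 * half
    raise ValueError(f"unknown convention {convention!r}")


def ln_bayes_factor(best: ModelScore, other: ModelScore) -> float:
    """ln marginal(best) - ln marginal(other); positive disfavours *other*."""
    _require(LN_MARGINAL, best, other)
    return best.value - other.value


@dataclass(frozen=True)
class ComparisonTable:
    """Models ranked best-first with differences against the best model."""

    reference: str
    table: pd.DataFrame = field(repr=False)

    def __str__(self):
        return self.table.to_string(index=False)


def rank_models(scores, aic_convention: str = "table2") -> ComparisonTable:
    """Rank scores best-first and tabulate LLR/dAIC or ln BF vs the best.

    Ties are broken by smaller K, then label.  All scores must share one
    score type.
    """
    scores = list(scores)
    if not scores:
        raise ValueError("no scores to rank")
    stype = scores[0].score_type
    _require(stype, *scores)
    ordered = sorted(
        scores, key=lambda s: (-s.value, s.K if s.K is not None else 0, s.label)
    )
    best = ordered[0]
    rows = []
    for s in ordered:
        row = {"model": s.label, stype: s.value}
        if stype == LN_MARGINAL:
            row["ln_BF"] = ln_bayes_factor(best, s)
            if s.sem is not None:
                row["sem"] = s.sem
        else:
            row["LLR"] = llr(best, s)
            if best.K is not None and s.K is not None:
                row["K"] = s.K
                row["dAIC"] = delta_aic(best, s, aic_convention)
        rows.append(row)
    return ComparisonTable(reference=best.label, table=pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# Stepping-stone marginal likelihood for tree models
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Priors:
    """Priors used by the stepping-stone sampler (recorded in reports).

    Branch lengths: iid exponential with mean ``branch_mean``.  Gamma
    shape: exponential with mean ``shape_mean`` (only when the model has
    more than one rate category).  Equilibrium frequencies: flat Dirichlet
    (only when ``sample_frequencies``).  The profile model uses
    ``profile_prior`` per column.
    """

    branch_mean: float = 0.1
    shape_mean: float = 1.0
    sample_frequencies: bool = False
    profile_prior: DirichletPrior = field(default_factory=DirichletPrior)


@dataclass(frozen=True)
class SteppingStoneSettings:
    """Chain-length and schedule knobs for the stepping-stone estimator.

    ``n_steps`` power-posterior steps with beta on the quantiles of
    Beta(schedule_alpha, 1); per step, ``burn`` discarded sweeps then
    ``samples`` recorded sweeps of Metropolis-within-Gibbs updates.
    """

    n_steps: int = 8
    burn: int = 2000
    samples: int = 10000
    schedule_alpha: float = 0.3
    proposal_sd: float = 0.5
    freq_concentration: float = 500.0
    n_batches: int = 10


def marginal_loglik_tree(
    h,
    a: Alignment,
    m: SubstitutionModel | None = None,
    priors: Priors | None = None,
    settings: SteppingStoneSettings | None = None,
    seed: int = 0,
    label: str | None = None,
) -> ModelScore:
    """ln marginal likelihood of a tree/forest/star/profile hypothesis.

    *h* may be an :class:`AncestryHypothesis` (a single tree — including a
    star tree — or a forest), a bare :class:`Tree`, or the string
    ``"profile"``.  The profile hypothesis dispatches to the analytic
    Dirichlet-multinomial marginal (sem = 0); tree hypotheses are
    estimated by stepping-stone sampling over branch lengths, with the
    gamma shape included whenever the model has > 1 rate category and
    frequencies included when the priors request it.  Forest marginals are
    sums of independent per-group marginals.
    """
    priors = priors or Priors()
    settings = settings or SteppingStoneSettings()
    if isinstance(h, str) and h == "profile":
        value = profile_marginal_loglik(a, priors.profile_prior)
        return ModelScore(label or "profile", LN_MARGINAL, value,
                          sem=0.0, family="profile")
    if isinstance(h, Tree):
        h = AncestryHypothesis.common_ancestry(h, label or "CA")
    if not isinstance(h, AncestryHypothesis):
        raise HypothesisError(f"cannot interpret hypothesis {h!r}")
    if m is None:
        raise HypothesisError("tree hypotheses require a substitution model")
    if h.taxa != set(a.names):
        raise HypothesisError("hypothesis taxa do not cover the alignment")

    rng = np.random.default_rng(seed)
    total, var = 0.0, 0.0
    for group, tree in zip(h.groups, h.trees):
        sub = a.restrict(group)
        if len(group) == 1:
            # no free parameters: the marginal is the stationary likelihood
            total += loglik(tree, sub, m)
            continue
        lnz, sem = _stepping_stone(tree, sub, m, priors, settings,
                                   np.random.default_rng(rng.integers(2**31)))
        total += lnz
        var += sem**2
    family = "star" if all(t.is_star for t in h.trees) else "tree"
    return ModelScore(label or h.label or "tree", LN_MARGINAL, total,
                      sem=float(np.sqrt(var)), family=family)


class _TreeState:
    """Mutable sampler state: branch lengths, optional shape/frequencies."""

    def __init__(self, tree, sub, model, priors, rng):
        from .treelik import PruningEngine

        self.tree = tree.copy()
        self.groups = free_edge_groups(self.tree)
        self.engine = PruningEngine(self.tree, sub, model, copy=False)
        self.priors = priors
        self.sample_shape = model.ncat > 1
        self.sample_freqs = priors.sample_frequencies
        self.model = model
        self.draw_from_prior(rng)

    def _set_group(self, group, value):
        self.engine.set_length(group[0], value)
        for n in group[1:]:
            self.engine.set_length(n, 0.0)

    def draw_from_prior(self, rng):
        for g in self.groups:
            set_group_length(g, _prior_branch(rng, self.priors.branch_mean))
        if self.sample_shape:
            shape = max(1e-3, rng.exponential(self.priors.shape_mean))
            self.model = self.model.with_shape(shape)
        if self.sample_freqs:
            pi = np.clip(rng.dirichlet(np.ones(20)), 1e-8, None)
            self.model = self.model.with_frequencies(pi / pi.sum())
        self.engine.set_model(self.model)  # full refresh after bulk changes
        self.ll = self.engine.loglik()

    def log_prior_branch(self, t):
        return -t / self.priors.branch_mean

    def sweep(self, beta, rng, sd, conc):
        """One Metropolis-within-Gibbs pass over all parameters."""
        for g in self.groups:
            t0 = get_group_length(g)
            t1 = t0 * np.exp(sd * rng.standard_normal())
            if not BRANCH_MIN <= t1 <= BRANCH_MAX:
                continue
            self._set_group(g, t1)
            ll1 = self.engine.loglik()
            # multiplicative proposal: Hastings term log(t1/t0)
            loga = (
                beta * (ll1 - self.ll)
                + self.log_prior_branch(t1) - self.log_prior_branch(t0)
                + np.log(t1) - np.log(t0)
            )
            if np.log(rng.random()) < loga:
                self.ll = ll1
            else:
                self._set_group(g, t0)
        if self.sample_shape:
            s0 = self.model.gamma.shape
            s1 = s0 * np.exp(sd * rng.standard_normal())
            if 1e-3 <= s1 <= 100.0:
                m1 = self.model.with_shape(s1)
                self.engine.set_model(m1)
                ll1 = self.engine.loglik()
                loga = (
                    beta * (ll1 - self.ll)
                    + (-(s1 - s0) / self.priors.shape_mean)
                    + np.log(s1) - np.log(s0)
                )
                if np.log(rng.random()) < loga:
                    self.model, self.ll = m1, ll1
                else:
                    self.engine.set_model(self.model)
        if self.sample_freqs:
            from scipy.stats import dirichlet as _dir

            pi0 = self.model.pi
            prop = rng.dirichlet(conc * pi0)
            if (prop > 1e-8).all():
                m1 = self.model.with_frequencies(prop)
                self.engine.set_model(m1)
                ll1 = self.engine.loglik()
                # flat Dirichlet prior cancels; Hastings ratio of proposals
                loga = (
                    beta * (ll1 - self.ll)
                    + _dir.logpdf(pi0, conc * prop)
                    - _dir.logpdf(prop, conc * pi0)
                )
                if np.log(rng.random()) < loga:
                    self.model, self.ll = m1, ll1
                else:
                    self.engine.set_model(self.model)


def _prior_branch(rng, mean):
    return float(np.clip(rng.exponential(mean), BRANCH_MIN, BRANCH_MAX))


def _stepping_stone(tree, sub, model, priors, settings, rng):
    """Stepping-stone ln-marginal estimate with a batch-means SEM."""
    K = settings.n_steps
    betas = (np.arange(K + 1) / K) ** (1.0 / settings.schedule_alpha)
    state = _TreeState(tree, sub, model, priors, rng)
    lnz, var = 0.0, 0.0
    for k in range(K):
        beta, dbeta = betas[k], betas[k + 1] - betas[k]
        lls = np.empty(settings.samples)
        if beta == 0.0:
            # the power posterior at beta=0 is the prior: iid draws
            for i in range(settings.samples):
                state.draw_from_prior(rng)
                lls[i] = state.ll
        else:
            for _ in range(settings.burn):
                state.sweep(beta, rng, settings.proposal_sd,
                            settings.freq_concentration)
            for i in range(settings.samples):
                state.sweep(beta, rng, settings.proposal_sd,
                            settings.freq_concentration)
                lls[i] = state.ll
        w = dbeta * lls
        lnz += logsumexp(w) - np.log(len(w))
        nb = min(settings.n_batches, len(w))
        batches = np.array_split(w, nb)
        est = np.array([logsumexp(b) - np.log(len(b)) for b in batches])
        var += est.var(ddof=1) / nb if nb > 1 else 0.0
    return float(lnz), float(np.sqrt(var))
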
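# Methods

## Models

**Substitution process.** All tree models use a time-reversible,
stationary, site-homogeneous Markov process on the 20 amino acids. A
rate matrix is assembled from symmetric exchangeabilities `s_ab` and
equilibrium frequencies `pi` as `Q_ab = s_ab·pi_b` (a ≠ b), diagonal set
so rows sum to zero, and normalized so that one unit of branch length
equals one expected substitution per site (`-Σ pi_a Q_aa = 1`).
Transition probabilities come from the symmetrized eigendecomposition
`D^{1/2} Q D^{-1/2}` (exact for reversible Q); entries are clamped at
zero and rows renormalized, which matters only at the 1e-15 level. WAG
and LG exchangeabilities are bundled in PAML `.dat` layout; `poisson`
(all exchangeabilities equal, uniform frequencies) is generated
programmatically. Rate heterogeneity uses the discrete-gamma
approximation with equal-weight categories and **mean** category rates
(the dominant convention in ML phylogenetics tools), renormalized to
mixture mean 1; the default category count is 4 when heterogeneity is
requested and 1 otherwise.

**Likelihood.** Felsenstein pruning with per-node rescaling; per-site
likelihoods are averaged over gamma categories; gaps and `X` are missing
data (all-ones conditionals) — the intended inputs are alignments with
ambiguous regions and indels removed, so no indel model is needed.
Trees are stored rooted but evaluated as unrooted: a degree-two root
contributes a single free branch (the two root edges are merged), which
makes the likelihood, the optimizer and the samplers agree with the
unrooted parameter count. A `PruningEngine` caches per-node partials
and per-edge messages so that changing one branch length only recomputes
the path to the root; the plain `loglik` entry point and the engine are
cross-checked against each other and against an exhaustive
state-enumeration oracle in the tests (≤ 5 leaves, tolerance 1e-9).

**Ancestry hypotheses.** A hypothesis is a partition of the taxa with
one tree per group. One group is common ancestry; several groups form an
independent-ancestry forest whose log-likelihood (or log marginal
likelihood) is the sum over groups — the groups share no parameters, so
the joint probability factorizes. Each group gets its own equilibrium
frequencies and gamma shape; this is what the per-group `19 + 1`
parameter counting assumes. Singleton groups contribute only the
stationary term `Σ log pi(residue)` and have no branch or shape
parameters. Parameter counting offers two conventions: `unrooted`
(2s−3 branches per group of size s ≥ 2, one branch for a pair) and
`table2_compat` (identical except pairs count two branches); four-taxon
examples give K = 25 (CA), 42 (1+3 splits), and 44 (2+2 splits under
`table2_compat`). Both are provided because published tables are
consistent only with the second for two-taxon groups; no intent is
guessed.

**Profile model.** Each column has its own categorical distribution over
the 20 residues — equivalent to an equal-branch star tree with a private
per-site process. The plug-in ML fit is `theta ∝ counts + pseudocount`;
the marginal likelihood under a symmetric Dirichlet prior is the exact
product of Dirichlet-multinomial evidences, `Π_s B(alpha + counts_s) /
B(alpha)`, computed in log-gamma arithmetic. The default prior is
**Jeffreys, alpha = 1/2**. A flat alpha = 1 contributes the equivalent
of 20 pseudo-observations per column; with ~12 sequences per column the
prior then outweighs the data and the profile model loses to tree models
even on data generated from a profile. Jeffreys is the standard
objective reference prior for a multinomial, keeps the evidence proper
and exchangeable, and restores posterior consistency at realistic
sample sizes. The prior is configurable, and the Monte-Carlo
integration oracle in the tests certifies the closed form under
whatever prior is set. Because the model spends 19 parameters per
column, requesting AIC/LLR comparisons that involve a profile model
raises a warning: with a data-to-parameter ratio of n/19 per column
(0.63 at n = 12) the asymptotic justification of those criteria fails;
Bayes factors do not have this problem.

## Model comparison

**Maximum likelihood.** Branch lengths are optimized by coordinate
ascent with bounded Brent steps on each free edge (bounds
[1e-8, 20], round tolerance 1e-6 lnL, ≤ 200 rounds), optionally
interleaved with gamma-shape optimization and either empirical or
softmax-parametrized ML frequencies per group. LLR is
`lnL(ca) − lnL(other)`; ΔAIC offers the half-AIC `(-lnL + K)` difference
(`table2` convention) and the standard doubled version.

**Marginal likelihoods.** Tree-model marginals use stepping-stone
sampling: beta follows the quantiles of Beta(0.3, 1) (default 8 steps);
at each power posterior a Metropolis-within-Gibbs chain updates each
free branch with multiplicative log-normal proposals (plus shape, plus
frequencies via a Dirichlet proposal when enabled), and each step's
ratio is estimated by log-sum-exp averaging with a batch-means standard
error; step variances add in quadrature. The beta = 0 step draws
i.i.d. from the prior. Priors: exponential(mean 0.1) on branch lengths,
exponential(mean 1) on the gamma shape, flat Dirichlet on frequencies;
they are recorded in every report. Defaults are 8 steps × (2000 burn +
10000 sampled) sweeps; the examples and tests use 4 × (60 + 250), which
resolves orderings whose gaps are tens to hundreds of log units (the
batch SEM is reported so under-resolved comparisons are visible). The
estimator is validated against deterministic quadrature on
single-branch models. In Bayes-factor comparisons the frequencies are
*sampled*, not fixed at empirical values: fixing them would hand every
tree model 19 fitted parameters free of any Occam penalty and bias the
comparison against the profile model. The profile hypothesis enters
with its analytic marginal (sem 0); forests sum per-group marginals.

**Similarity statistics.** Optimal global/local alignment with affine
gaps (BLOSUM62 default, gap open 11 / extend 1, a length-k gap costing
`open + k·extend`) is delegated to Biopython's `PairwiseAligner` and
verified against brute-force enumeration for short sequences. The null
distribution is built from composition-preserving shuffles of one
sequence, a Gumbel is fitted by maximum likelihood, and
`P = 1 − exp(−exp(−(S−mu)/beta))`, `E = −ln(1−P)` (computed as
`exp(−z)` to avoid cancellation). E-values are deliberately empirical
(no analytic lambda/K, no database-size correction), so they are
self-contained and reproducible but not comparable to search-engine
E-values.

## Synthetic data

`simulate_on_tree` draws root states from `pi`, applies `P(t·r_c)` per
edge, with one gamma category per site shared across the whole tree.
`simulate_forest` gives each group an independent spawned RNG stream, so
adding or changing one group never perturbs another. `simulate_profile`
draws each cell independently from its column distribution, one stream
per sequence.

**Conflicting-signal generator.** Column by column, one of the three
two-pair partitions of four taxa is chosen by weight; each pair draws a
residue (identical within the pair with probability `within_identity`),
the two pairs independent. In the default (background) mode all draws
come from one distribution, giving the closed-form pairwise identity
`1/3 + 2/3·Σ pi²` at `within_identity = 1`. In this mode, however, a
single tree always fits at least as well as a two-pair forest with the
same frequencies — a four-taxon tree with a long internal branch
decouples its two cherries and so *contains* the forest as a limit,
while additionally modelling the four cross-pair correlations. The
regime in which independent ancestry genuinely wins is
composition-driven: with `domain_concentration` set, each of the six
(pairing, pair) combinations — six distinct "domains" — has its own
concentrated residue distribution (Dirichlet draws boosted on a private
block of residues), so every sequence has an idiosyncratic composition
that per-group frequency parameters fit and shared-frequency trees
cannot. The fixture scenario defaults to this construction
(concentration 0.05, `within_identity` 0.3, weights 0.4/0.3/0.3,
L = 1000), which yields LLRs of order −100 to −600 in favour of the
matching two-pair forest. This generator reproduces the *behaviour*
(signs and orderings) of such four-sequence counterexamples, not any
particular published sequence set.

**Permutation control.** Residues are permuted within each ungapped
sequence (composition preserved exactly) and the shuffles re-aligned
from scratch by progressive profile-profile alignment: pairwise global
scores define a greedy single-linkage merge order (ties by label), and
blocks are merged by affine-gap dynamic programming on mean pairwise
column scores. Any CA-vs-IA preference that survives is attributable to
the alignment procedure; on tree-simulated data the residual is a few
percent to ~15% of the genuine signal.

**Study conditions in the recovery tests** (chosen once as realistic
analogues and frozen): the profile-data experiment fits its generating
profile (pseudocount 0, plain observed frequencies) to a WAG simulation
on a deep 12-taxon tree (root-to-tip ~0.9) and draws 12 × 300
alignments — deep divergence gives variable columns, the regime where a
profile source is distinguishable from a tree; the tree-data experiment
uses a 6-taxon tree with a long (0.75 per side) inter-group stem,
mirroring data sets whose groups are separated by very deep divergence,
evaluated at L = 500. Orderings are demanded in ≥ 9 of 10 seeded
replicates. Chain lengths in these tests (4 steps, 60 + 250 sweeps) are
chosen so the stepping-stone SEM (~5–25 log units) is small against the
ordering gaps (~60–1000).

## What the simulations do and do not show

The generators produce gap-free, equal-length, site-independent data
under exactly the model families being compared (plus the conflicting
construction, which none of the fitted models generates). Passing the
recovery tests shows the estimators and the comparison logic are
correct and calibrated at these scales; it does not show that real
proteins satisfy site independence, homogeneity or reversibility, nor
does it address alignment uncertainty beyond the permutation bound.
Absolute marginal-likelihood values depend on the stated priors; only
differences (Bayes factors) are reported as evidence.

## Numerical choices and limitations

Branch lengths live in [1e-8, 20]; per-site scaling keeps partials in
range at any depth; optimization is deterministic given inputs;
samplers and simulators are deterministic given a seed (spawned
substreams per group/sequence/chain). Topology search is limited to
exhaustive enumeration (≤ 7 taxa) or a neighbor-joining guide tree from
p-distances — the package's contribution is model comparison, not tree
search. Known limitations: no indel model, no covarion/heterotachy, no
codon models, no CAT-style mixtures beyond the fixed per-column
profile, no analytic Karlin–Altschul parameters for gapped alignments,
and the stepping-stone SEM is a batch-means estimate that can be
optimistic for short, poorly mixing chains (the seeded-replicate
agreement test guards against gross failure).
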
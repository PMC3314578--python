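"""Karlin-Altschul-style similarity statistics.

Optimal pairwise alignment scores under a log-odds scoring matrix, an
empirical null distribution from composition-preserving shuffles, a
maximum-likelihood Gumbel (extreme value) fit to the null scores, and the
resulting tail P-values and E-values (E = -ln(1 - P)).  This is the
null-hypothesis machinery that model-selection tests of ancestry are
contrasted with: a small E-value says the similarity is unlikely under
randomly shuffled sequences, nothing more.

E-values here come from the empirically fitted EVD rather than analytic
Karlin-Altschul lambda/K with database-size corrections, so they are
self-contained and reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices
from scipy.stats import gumbel_r

from .errors import MatrixFormatError
from .seqio import AMINO_ACIDS, AA_INDEX


@dataclass(frozen=True)
class ScoringMatrix:
    """Symmetric 20x20 substitution scores with affine gap penalties.

    Gap cost of a length-k gap is ``gap_open + k * gap_extend`` (BLAST
    convention).
    """

    scores: np.ndarray = field(repr=False)
    gap_open: float = 11.0
    gap_extend: float = 1.0
    name: str = ""

    def __post_init__(self):
        s = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", s)
        if s.shape != (20, 20):
            raise MatrixFormatError(f"scores must be 20x20, got {s.shape}")
        if not np.allclose(s, s.T):
            raise MatrixFormatError("scoring matrix must be symmetric")
        if self.gap_open < 0 or self.gap_extend < 0:
            raise MatrixFormatError("gap penalties must be >= 0")

    def score(self, a: str, b: str) -> float:
        return float(self.scores[AA_INDEX[a], AA_INDEX[b]])

    def expected_score(self, freqs=None) -> float:
        """Expected per-position score under background frequencies."""
        f = np.full(20, 1 / 20) if freqs is None else np.asarray(freqs)
        return float(f @ self.scores @ f)


def read_ncbi_matrix(path, gap_open: float = 11.0, gap_extend: float = 1.0) -> ScoringMatrix:
    """Read an NCBI-format scoring matrix text file (e.g. BLOSUM62)."""
    header: list[str] | None = None
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip()
            if not line or line.lstrip().startswith("#"):
                continue
            parts = line.split()
            if header is None:
                header = parts
                continue
            key, *vals = parts
            try:
                rows[key] = [float(v) for v in vals[: len(header)]]
            except ValueError:
                raise MatrixFormatError(f"{path}:{lineno}: non-numeric score") from None
    if header is None:
        raise MatrixFormatError(f"{path}: empty matrix file")
    missing = set(AMINO_ACIDS) - set(header) | (set(AMINO_ACIDS) - set(rows))
    if missing:
        raise MatrixFormatError(f"{path}: missing residues {sorted(missing)}")
    col = {aa: header.index(aa) for aa in AMINO_ACIDS}
    s = np.array([[rows[a][col[b]] for b in AMINO_ACIDS] for a in AMINO_ACIDS])
    return ScoringMatrix(s, gap_open, gap_extend, name=str(path))


def blosum62(gap_open: float = 11.0, gap_extend: float = 1.0) -> ScoringMatrix:
    """The bundled BLOSUM62 matrix with BLAST-default affine penalties."""
    ref = resources.files("phyloca.data") / "blosum62.txt"
    with resources.as_file(ref) as p:
        m = read_ncbi_matrix(p, gap_open, gap_extend)
    return ScoringMatrix(m.scores, gap_open, gap_extend, name="BLOSUM62")


def _aligner(matrix: ScoringMatrix, mode: str) -> Align.PairwiseAligner:
    if mode not in ("global", "local"):
        raise ValueError(f"mode must be 'global' or 'local', got {mode!r}")
    sub = substitution_matrices.Array(alphabet=AMINO_ACIDS, dims=2)
    for i, a in enumerate(AMINO_ACIDS):
        for j, b in enumerate(AMINO_ACIDS):
            sub[a, b] = matrix.scores[i, j]
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = sub
    aligner.open_gap_score = -(matrix.gap_open + matrix.gap_extend)
    aligner.extend_gap_score = -matrix.gap_extend
    return aligner


def align_pair(s1: str, s2: str, matrix: ScoringMatrix | None = None,
               mode: str = "global"):
    """Optimal pairwise alignment -> ((aligned1, aligned2), score).

    Needleman-Wunsch (global) or Smith-Waterman (local) with affine gaps.
    """
    matrix = matrix or blosum62()
    s1, s2 = s1.upper(), s2.upper()
    for s in (s1, s2):
        if not s:
            raise ValueError("sequences must be non-empty")
        bad = set(s) - set(AMINO_ACIDS)
        if bad:
            raise ValueError(f"illegal residue(s) {sorted(bad)}")
    aligner = _aligner(matrix, mode)
    alignments = aligner.align(s1, s2)
    best = alignments[0]
    a1, a2 = str(best[0]), str(best[1])
    return (a1, a2), float(best.score)


def alignment_score(s1: str, s2: str, matrix: ScoringMatrix | None = None,
                    mode: str = "global") -> float:
    """Optimal alignment score only (cheaper than building the alignment)."""
    matrix = matrix or blosum62()
    return float(_aligner(matrix, mode).score(s1.upper(), s2.upper()))


def null_scores(s1: str, s2: str, n_shuffles: int, seed: int = 0,
                matrix: ScoringMatrix | None = None,
                mode: str = "global") -> np.ndarray:
    """Scores of *s1* against composition-preserving shuffles of *s2*."""
    if n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    matrix = matrix or blosum62()
    rng = np.random.default_rng(seed)
    chars = np.array(list(s2.upper()))
    aligner = _aligner(matrix, mode)
    out = np.empty(n_shuffles)
    for i in range(n_shuffles):
        out[i] = aligner.score(s1.upper(), "".join(rng.permutation(chars)))
    return out


@dataclass(frozen=True)
class EVDParams:
    """Gumbel location/scale fitted to null alignment scores."""

    mu: float
    beta: float

    def __post_init__(self):
        if self.beta <= 0:
            raise ValueError(f"scale must be > 0, got {self.beta}")


def fit_evd(scores) -> EVDParams:
    """Maximum-likelihood Gumbel fit to a sample of null scores."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 30:
        raise ValueError(f"need >= 30 scores, got {scores.size}")
    if np.ptp(scores) == 0:
        raise ValueError("scores are constant; cannot fit an EVD")
    mu, beta = gumbel_r.fit(scores)
    return EVDParams(float(mu), float(beta))


def pvalue(S_o: float, evd: EVDParams) -> float:
    """Tail probability P(S >= S_o) under the fitted EVD."""
    return float(gumbel_r.sf(S_o, loc=evd.mu, scale=evd.beta))


def evalue(P: float) -> float:
    """E = -ln(1 - P)."""
    if not 0 <= P < 1:
        raise ValueError(f"P must be in [0, 1), got {P}")
    return float(-np.log1p(-P))


def pvalue_from_evalue(E: float) -> float:
    """Inverse of :func:`evalue`: P = 1 - exp(-E)."""
    if E < 0:
        raise ValueError(f"E must be >= 0, got {E}")
    return float(-np.expm1(-E))


def evalue_from_score(S_o: float, evd: EVDParams) -> float:
    """E-value of an observed score: exact tail computation, -ln(1 - P)."""
    # 1 - P = exp(-exp(-z)) so E = exp(-z) without cancellation
    z = (S_o - evd.mu) / evd.beta
    return float(np.exp(-z))
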
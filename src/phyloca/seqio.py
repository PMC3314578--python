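"""Protein alignment I/O and per-column count statistics.

Alignments are immutable collections of equal-length amino-acid sequences
over the 20-letter alphabet plus ``-`` (gap) and ``X`` (unknown residue).
Gaps and unknowns are treated as missing data throughout the package: they
contribute nothing to likelihoods or column counts.  The residue order is
the canonical PAML order ``ARNDCQEGHILKMFPSTWYV`` so that rate-matrix files
map onto count vectors without reindexing.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
from Bio import AlignIO, SeqIO

from .errors import IllegalSymbolError, RaggedAlignmentError, SequenceFormatError

#: Canonical amino-acid ordering (PAML / .dat file convention).
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
GAP = "-"
UNKNOWN = "X"
#: Integer code used for missing data in encoded alignments.
MISSING_CODE = 20

_VALID = set(AMINO_ACIDS) | {GAP, UNKNOWN}


@dataclass(frozen=True)
class Alignment:
    """An n x L protein alignment with unique taxon labels.

    Symbols are stored uppercase; ``-`` and ``X`` are missing data.
    """

    names: tuple[str, ...]
    rows: tuple[str, ...]

    def __post_init__(self):
        if len(self.names) != len(self.rows):
            raise SequenceFormatError("names and rows differ in number")
        if len(self.names) == 0:
            raise SequenceFormatError("alignment must contain at least one sequence")
        if any(not n for n in self.names):
            raise SequenceFormatError("taxon labels must be non-empty")
        if len(set(self.names)) != len(self.names):
            dup = sorted({n for n in self.names if self.names.count(n) > 1})
            raise SequenceFormatError(f"duplicate taxon labels: {dup}")
        rows = tuple(r.upper() for r in self.rows)
        object.__setattr__(self, "rows", rows)
        lengths = {len(r) for r in rows}
        if len(lengths) != 1:
            raise RaggedAlignmentError(
                "sequences have unequal lengths: "
                + ", ".join(f"{n}={len(r)}" for n, r in zip(self.names, rows))
            )
        if next(iter(lengths)) < 1:
            raise SequenceFormatError("alignment length must be >= 1")
        for name, row in zip(self.names, rows):
            bad = set(row) - _VALID
            if bad:
                raise IllegalSymbolError(
                    f"illegal symbol(s) {sorted(bad)} in sequence {name!r}"
                )

    @property
    def n_sequences(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def sequence(self, name: str) -> str:
        try:
            return self.rows[self.names.index(name)]
        except ValueError:
            raise KeyError(f"no sequence named {name!r}") from None

    def restrict(self, names) -> "Alignment":
        """Sub-alignment containing only *names*, in alignment order."""
        keep = set(names)
        missing = keep - set(self.names)
        if missing:
            raise KeyError(f"taxa not in alignment: {sorted(missing)}")
        pairs = [(n, r) for n, r in zip(self.names, self.rows) if n in keep]
        return Alignment(tuple(n for n, _ in pairs), tuple(r for _, r in pairs))

    def column(self, site: int) -> str:
        if not 0 <= site < self.length:
            raise IndexError(f"site {site} out of range [0, {self.length})")
        return "".join(r[site] for r in self.rows)

    def encoded(self) -> np.ndarray:
        """(n, L) integer matrix; residues 0..19 in PAML order, missing = 20."""
        out = np.empty((self.n_sequences, self.length), dtype=np.int8)
        for i, row in enumerate(self.rows):
            out[i] = [AA_INDEX.get(c, MISSING_CODE) for c in row]
        return out


@dataclass(frozen=True)
class ColumnCounts:
    """Sufficient statistics of one alignment column (gaps/X excluded)."""

    site: int
    counts: np.ndarray = field(repr=False)
    n_observed: int = 0

    def __post_init__(self):
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (20,) or (c < 0).any():
            raise ValueError("counts must be 20 non-negative integers")
        if c.sum() != self.n_observed:
            raise ValueError("counts must sum to n_observed")


def column_counts(a: Alignment, site: int) -> ColumnCounts:
    """Residue counts at one column; gaps and 'X' are excluded."""
    col = a.column(site)
    counts = np.zeros(20, dtype=int)
    for c in col:
        i = AA_INDEX.get(c)
        if i is not None:
            counts[i] += 1
    return ColumnCounts(site=site, counts=counts, n_observed=int(counts.sum()))


def all_column_counts(a: Alignment) -> np.ndarray:
    """(L, 20) count matrix for every column at once."""
    enc = a.encoded()
    counts = np.zeros((a.length, 20), dtype=int)
    for code in range(20):
        counts[:, code] = (enc == code).sum(axis=0)
    return counts


# ---------------------------------------------------------------------------
# File formats.  FASTA and PHYLIP parsing is delegated to Biopython; the
# wrappers add validation and the package's error types.
# ---------------------------------------------------------------------------

def read_fasta(path) -> Alignment:
    """Read a FASTA file (wrapped or unwrapped) into an :class:`Alignment`."""
    with open(path) as fh:
        text = fh.read()
    if not text.strip():
        raise SequenceFormatError(f"{path}: empty file")
    if not text.lstrip().startswith(">"):
        raise SequenceFormatError(f"{path}: not FASTA (missing '>' header)")
    records = list(SeqIO.parse(io.StringIO(text), "fasta"))
    if not records:
        raise SequenceFormatError(f"{path}: no FASTA records found")
    for rec in records:
        if not rec.id:
            raise SequenceFormatError(f"{path}: record with empty header")
    return Alignment(
        tuple(rec.id for rec in records),
        tuple(str(rec.seq) for rec in records),
    )


def write_fasta(a: Alignment, path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, row in zip(a.names, a.rows):
            fh.write(f">{name}\n")
            for i in range(0, len(row), width):
                fh.write(row[i : i + width] + "\n")


def read_phylip(path) -> Alignment:
    """Read sequential or interleaved (relaxed) PHYLIP."""
    with open(path) as fh:
        text = fh.read()
    header = text.split("\n", 1)[0].split()
    if len(header) < 2:
        raise SequenceFormatError(f"{path}: missing PHYLIP 'n L' header line")
    try:
        n, L = int(header[0]), int(header[1])
    except ValueError:
        raise SequenceFormatError(f"{path}: non-numeric PHYLIP header {header!r}")
    last_err = None
    for schema in ("phylip-relaxed", "phylip-sequential", "phylip"):
        try:
            msa = AlignIO.read(io.StringIO(text), schema)
        except Exception as exc:  # biopython raises bare ValueError
            last_err = exc
            continue
        if len(msa) != n or msa.get_alignment_length() != L:
            continue
        return Alignment(
            tuple(rec.id for rec in msa), tuple(str(rec.seq) for rec in msa)
        )
    raise SequenceFormatError(
        f"{path}: body does not match header n={n}, L={L} ({last_err})"
    )


def write_phylip(a: Alignment, path) -> None:
    """Write relaxed sequential PHYLIP."""
    with open(path, "w") as fh:
        fh.write(f" {a.n_sequences} {a.length}\n")
        pad = max(len(n) for n in a.names) + 2
        for name, row in zip(a.names, a.rows):
            fh.write(name.ljust(pad) + row + "\n")
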
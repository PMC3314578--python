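"""Exception hierarchy shared across the package."""


class PhylocaError(Exception):
    """Base class for all package-specific errors."""


class SequenceFormatError(PhylocaError, ValueError):
    """Malformed alignment file (bad header, syntax, etc.)."""


class RaggedAlignmentError(SequenceFormatError):
    """Sequences in one alignment have unequal lengths."""


class IllegalSymbolError(SequenceFormatError):
    """A residue outside the amino-acid alphabet (plus '-'/'X')."""


class MatrixFormatError(PhylocaError, ValueError):
    """Malformed rate-matrix or scoring-matrix file."""


class NewickError(PhylocaError, ValueError):
    """Malformed Newick tree text."""


class HypothesisError(PhylocaError, ValueError):
    """Invalid ancestry hypothesis (bad partition, missing taxa...)."""


class ModelError(PhylocaError, ValueError):
    """Invalid substitution-model parameters."""
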
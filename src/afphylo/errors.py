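"""Exception hierarchy.

Every failure mode the pipeline can hit maps to a distinct, message-bearing
exception so that callers (and the CLI) can react precisely.
"""


class AfphyloError(Exception):
    """Base class for all package errors."""


class ParameterError(AfphyloError, ValueError):
    """Invalid parameter combination (bad k, M, measure, thread settings...)."""


class FastaError(AfphyloError):
    """Malformed or unusable FASTA input."""


class EmptyInputError(FastaError):
    """A FASTA file with no records, or an empty sequence collection."""


class EmptySequenceError(FastaError):
    """A FASTA record whose sequence body is empty."""


class DuplicateIdError(FastaError):
    """Two FASTA records share the same identifier."""


class UndefinedDistanceError(AfphyloError):
    """A pairwise distance is mathematically undefined for this input
    (zero spectrum, all words dropped, zero-norm composition vector)."""


class MatrixError(AfphyloError):
    """A distance matrix violating its contract (asymmetry, NaN, bad shape)."""


class LabelError(AfphyloError):
    """Leaf-label problems: duplicates within a tree, or mismatched label
    sets between two trees being compared."""
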
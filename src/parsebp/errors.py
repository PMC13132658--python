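"""Exception hierarchy for ensemble scoring."""


class ParsebpError(Exception):
    """Base class for all package-specific errors."""


class StructureParseError(ParsebpError):
    """A coordinate file could not be read."""


class EmptyStructureError(ParsebpError):
    """A coordinate file contained no usable nucleotide residues."""


class EnsembleTooSmallError(ParsebpError):
    """Fewer than two mutually consistent decoys were found."""


class CorrespondenceError(ParsebpError):
    """Two structures (or maps) cannot be put in 1:1 residue correspondence."""


class DegenerateFitError(ParsebpError):
    """Too few points for a rigid-body superposition."""


class PairAnnotationError(ParsebpError):
    """A base-pair list file is malformed or out of range."""


class PairEvaluationError(ParsebpError):
    """A pairwise similarity evaluation failed for a specific decoy pair."""


class MatrixAlignmentError(ParsebpError):
    """Two similarity matrices do not share identifiers/order."""


class EvaluationInputError(ParsebpError):
    """An evaluation table is missing required columns or values."""
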
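"""Exception hierarchy for the pipeline.

Every error raised by this package derives from :class:`OrchidEdgeError`,
so callers (and the CLI) can distinguish data problems from genuine bugs.
"""


class OrchidEdgeError(Exception):
    """Base class for all package errors."""


class FormatError(OrchidEdgeError):
    """A file could not be parsed (malformed Newick, FASTA, CSV...)."""


class ValidationError(OrchidEdgeError):
    """Parsed data violates a structural contract (duplicate labels,
    unknown Red List category, unmapped accession...)."""


class AlignmentError(OrchidEdgeError):
    """Sequences that must be aligned have unequal lengths."""


class SaturationError(OrchidEdgeError):
    """A pairwise distance is undefined because the K2P log arguments
    are non-positive (substitution saturation)."""


class InsufficientDataError(OrchidEdgeError):
    """Too few usable observations for the requested statistic."""


class DegeneratePredictorError(OrchidEdgeError):
    """A regression/correlation predictor has zero variance."""


class CalibrationError(OrchidEdgeError):
    """A requested simulation target is unattainable (e.g. a rank
    correlation beyond what a thresholded binary trait can express)."""
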
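"""Exception hierarchy for the MMS pipeline."""


class FaceMMSError(Exception):
    """Base class for all pipeline errors."""


class FormatError(FaceMMSError):
    """Input table does not match the expected OpenFace dialect."""


class EmptyInputError(FaceMMSError):
    """Input has no data rows."""


class OrderingError(FaceMMSError):
    """Timestamps are not strictly increasing."""


class DataQualityError(FaceMMSError):
    """Input values violate a quality constraint (e.g. too many failed frames)."""


class DegenerateFrameError(FaceMMSError):
    """A frame has zero coordinate variance on some axis."""


class InsufficientDataError(FaceMMSError):
    """Too few samples for the requested operation."""


class DegenerateFitError(FaceMMSError):
    """Distribution fit undefined (e.g. zero sample variance)."""


class FitFailureError(FaceMMSError):
    """Maximum-likelihood optimisation failed to converge."""


class IncompleteRegionError(FaceMMSError):
    """A region is missing landmark speed series required for gluing."""


class IncompleteSignatureError(FaceMMSError):
    """A participant/task is missing a fitted region signature."""


class DomainError(FaceMMSError):
    """Argument outside the operation's domain."""
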
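"""Exception hierarchy for the pipeline."""


class CuttlekinError(Exception):
    """Base class for all package errors."""


class FormatError(CuttlekinError):
    """A file does not follow the expected dialect (e.g. missing body part)."""


class ParseError(CuttlekinError):
    """A cell could not be parsed; message carries row/column."""


class ValidationError(CuttlekinError):
    """Data violates a documented invariant (e.g. likelihood outside [0, 1])."""


class ParameterError(CuttlekinError):
    """A parameter is outside its documented range."""


class DegenerateGeometryError(CuttlekinError):
    """A geometric construction collapsed (zero-length vector, coincident points)."""


class InsufficientDataError(CuttlekinError):
    """Too few frames/samples for the requested operation."""


class UnrecoverablePartError(CuttlekinError):
    """A body part has no observed frame at all; interpolation impossible."""


class DegenerateSampleError(CuttlekinError):
    """A statistical sample is degenerate (e.g. all paired differences zero)."""


class ScenarioError(CuttlekinError):
    """A simulation scenario is internally inconsistent."""


class IntegrityError(CuttlekinError):
    """A packaged fixture fails its integrity counts."""
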
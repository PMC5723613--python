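"""Exception hierarchy for the pipeline."""


class DiveboutError(Exception):
    """Base class for all package errors."""


class FormatError(DiveboutError):
    """A file does not conform to the expected dialect (e.g. missing column)."""


class DataError(DiveboutError):
    """The data violate an invariant (non-monotone time, overlapping dives...)."""


class CoverageError(DiveboutError):
    """A point or interval falls outside the spatial/temporal domain of a grid or track."""


class MatchError(DiveboutError):
    """A dive could not be matched to a regularized GPS fix."""


class FitError(DiveboutError):
    """A statistical fit failed or was handed degenerate input."""
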
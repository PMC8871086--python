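"""Exception hierarchy for the histoscar pipeline.

Every error raised by the library derives from :class:`HistoscarError`, so
callers (in particular the CLI) can distinguish pipeline failures from
programming errors.
"""


class HistoscarError(Exception):
    """Base class for all histoscar errors."""


class InputFormatError(HistoscarError):
    """An input file is unreadable, truncated, or in a rejected format."""


class BoundsError(HistoscarError):
    """An ROI box falls outside the image frame."""


class DimensionError(HistoscarError):
    """Arrays that must share a frame have mismatched shapes."""


class ParameterError(HistoscarError):
    """A numeric or categorical parameter violates a precondition."""


class DegenerateInputError(HistoscarError):
    """Input lacks the variability an operation requires (e.g. < 3 distinct colors)."""


class AmbiguousRolesError(HistoscarError):
    """Two clusters have indistinguishable mean lightness; roles cannot be assigned."""


class DegenerateVarianceError(HistoscarError):
    """A statistical test's variance term is zero while means differ."""
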
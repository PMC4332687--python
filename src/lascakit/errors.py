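"""Exception hierarchy.

Every error raised on purpose by lascakit derives from :class:`LascaError`,
so callers can catch one type at pipeline level while tests can still
distinguish the specific failure mode.
"""


class LascaError(Exception):
    """Base class for all lascakit errors."""


class FormatError(LascaError):
    """Unreadable or unsupported image file."""


class ChannelPolicyError(LascaError):
    """Channel policy incompatible with the image (e.g. 'single' on RGB)."""


class BoundsError(LascaError):
    """Rectangle or region exceeds image bounds."""


class ParameterError(LascaError):
    """Invalid parameter value (window, fraction, config field...)."""


class SampleSizeError(ParameterError):
    """Too few observations for the requested statistic."""


class DegenerateInputError(LascaError):
    """Input with no variability where spread is required."""


class InsufficientDataError(LascaError):
    """Fewer usable contrast cells than the configured minimum."""


class DomainError(LascaError):
    """Value outside the mathematical domain of an operation."""


class ConsistencyError(LascaError):
    """Mutually inconsistent inputs (mixed groups, overlapping regions...)."""


class RunError(LascaError):
    """Fatal end-to-end pipeline failure."""
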
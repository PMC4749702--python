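"""Exception hierarchy.

All domain errors derive from :class:`FractopathError` so callers can catch
one base class; each also derives from ``ValueError`` so that sloppy inputs
fail loudly with the standard library idiom.
"""


class FractopathError(ValueError):
    """Base class for all errors raised by fractopath."""


class FormatError(FractopathError):
    """An image file exists but cannot be decoded."""


class DegenerateInputError(FractopathError):
    """The input is valid but the quantity is undefined on it.

    Examples: a constant image has no threshold; an empty foreground has no
    box counts; a single-pixel image has no adjacent pixel pairs.
    """


class InsufficientScalesError(FractopathError):
    """Fewer than three scales available for a log-log regression."""


class LabelError(FractopathError):
    """Group labels do not define at least two non-empty groups."""


class PackingError(FractopathError):
    """A synthetic tissue spec asks for more glands than fit the canvas."""


class SpecError(FractopathError):
    """A synthetic cohort spec is internally inconsistent."""
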
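"""Exception hierarchy.

All errors raised deliberately by this package derive from :class:`MvgremlError`,
so callers (and the CLI) can distinguish user-facing problems from bugs.
"""


class MvgremlError(Exception):
    """Base class for all mvgreml errors."""


class FormatError(MvgremlError):
    """A file does not conform to its on-disk format."""


class InputError(MvgremlError):
    """Inputs are syntactically valid but mutually inconsistent or out of range."""


class ModelSpecificationError(MvgremlError):
    """A factor-model specification cannot be fitted (identification, PSD, ...)."""


class NumericalError(MvgremlError):
    """A numerical operation failed beyond the configured fallbacks."""
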
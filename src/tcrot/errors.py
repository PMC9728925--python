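"""Exception hierarchy shared across the package.

All user-input problems derive from :class:`ValidationError` so the CLI can
map them to a common exit code.
"""


class TcrotError(Exception):
    """Base class for package errors."""


class ValidationError(TcrotError, ValueError):
    """Invalid user input (bad characters, bad parameters, bad shapes)."""


class InputFormatError(ValidationError):
    """A clonotype table is missing required columns or is malformed."""


class ResolutionError(ValidationError):
    """A TRBV allele cannot be resolved against the germline loop table."""


class SizeError(TcrotError):
    """An instance exceeds the guard limit of an exact (cubic-cost) solver."""
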
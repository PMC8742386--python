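"""Exception hierarchy.

All data-level failures raise :class:`SnpEnrichError` (a ``ValueError``), so
callers and the CLI can distinguish malformed/inconsistent inputs (exit code 2)
from usage mistakes (exit code 1).
"""


class SnpEnrichError(ValueError):
    """Base class for data and consistency errors raised by this package."""


class InputFormatError(SnpEnrichError):
    """A file did not conform to its expected dialect (bad column, bad value)."""


class EmptyResultError(SnpEnrichError):
    """An operation that requires at least one usable record found none."""
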
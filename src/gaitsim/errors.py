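"""Exception hierarchy.

Everything raised on bad input derives from :class:`GaitSimError` so callers
can catch one base class; each subclass also derives from ``ValueError`` to
behave sensibly for callers that don't know about the package.
"""


class GaitSimError(Exception):
    """Base class for all package-specific errors."""


class SupportMismatchError(GaitSimError, ValueError):
    """Two fuzzy sets do not share the same ordered support."""


class EmptyInputError(GaitSimError, ValueError):
    """An operation received an empty support, sample, or vector."""


class DimensionMismatchError(GaitSimError, ValueError):
    """Data vectors of different dimension were compared."""


class DegenerateInputError(GaitSimError, ValueError):
    """Input admits no meaningful normalization (e.g. all pairwise distances zero)."""


class MissingChannelError(GaitSimError, ValueError):
    """A recording lacks a channel required by the operation."""


class SynchronizationError(GaitSimError, ValueError):
    """Recordings have no overlapping window after lag compensation."""


class CohortError(GaitSimError, ValueError):
    """A cohort is incomplete or inconsistent; message lists what is missing."""


class ParseError(GaitSimError, ValueError):
    """A file failed validation; message names the offending row/column."""
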
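"""Exception hierarchy.

All package errors derive from :class:`GrowthLawError` so callers can catch
one base class; each subclass also derives from ``ValueError`` because every
failure mode here is ultimately a bad input or a degenerate configuration.
"""


class GrowthLawError(Exception):
    """Base class for all growthlaw errors."""


class DomainError(GrowthLawError, ValueError):
    """A physical-domain violation (e.g. length above L_max, negative k)."""


class InsufficientDataError(GrowthLawError, ValueError):
    """Too few observations for the requested operation."""


class DegenerateDesignError(GrowthLawError, ValueError):
    """Regression design matrix is rank deficient (e.g. all lengths equal)."""


class MalformedInputError(GrowthLawError, ValueError):
    """An input file or config could not be parsed; message names the spot."""


class UnitMismatchError(GrowthLawError, ValueError):
    """Quantities with incompatible declared units were combined."""
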
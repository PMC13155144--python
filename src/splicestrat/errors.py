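"""Exception hierarchy shared across the package.

Every error raised on bad user input derives from :class:`SpliceStratError`
so callers can catch one base class; subclasses distinguish parse-time,
data-integrity, and model-fitting failures.
"""


class SpliceStratError(Exception):
    """Base class for all package-specific errors."""


class ParseError(SpliceStratError, ValueError):
    """A string or file token could not be parsed."""


class FormatError(SpliceStratError, ValueError):
    """A structured input file violates its format contract."""


class DataError(SpliceStratError, ValueError):
    """Input values violate a data invariant (negative counts, NaNs, ...)."""


class UsageError(SpliceStratError, ValueError):
    """An operation was called with arguments outside its contract."""


class DefinitionError(SpliceStratError, ValueError):
    """An isoform definition is internally inconsistent."""


class DesignError(SpliceStratError, ValueError):
    """A regression design matrix is unusable (constant column, ...)."""


class ConvergenceError(SpliceStratError, RuntimeError):
    """An iterative fit failed to converge (e.g. monotone likelihood)."""


class JoinError(SpliceStratError, KeyError):
    """Sample barcodes could not be joined across tables."""


class ConfigError(SpliceStratError, ValueError):
    """A configuration object or file is invalid."""
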
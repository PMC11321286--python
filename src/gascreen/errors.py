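"""Exception hierarchy shared across the package.

Everything user-facing derives from :class:`GascreenError` so callers (and
the CLI) can distinguish data/usage problems from genuine bugs.
"""


class GascreenError(Exception):
    """Base class for all errors raised by gascreen."""


class GeometryError(GascreenError):
    """Scan geometry is invalid or inconsistent with an array's shape."""


class InvalidConfigError(GascreenError):
    """A configuration object violates its invariants."""


class IncompleteRecordError(GascreenError):
    """An eye or patient record is missing data a computation requires."""


class DataError(GascreenError):
    """Malformed or inconsistent on-disk data (parse errors carry location)."""


class SampleShortfallError(GascreenError):
    """A validation stratum's eligible pool is smaller than the requested n."""


class CoverageError(GascreenError):
    """A yield inference target covers a stratum absent from the table."""


class UndefinedStatisticError(GascreenError):
    """A statistic is undefined for the given input (e.g. PPV with n=0)."""


class InsufficientDataError(GascreenError):
    """Too few observations for the requested analysis."""
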
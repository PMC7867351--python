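"""Exception hierarchy shared across the package."""


class SoilmatchError(Exception):
    """Base class for all soilmatch errors."""


class ValidationError(SoilmatchError):
    """A record, query, or configuration violates its invariants."""


class ParseError(SoilmatchError):
    """Database text could not be parsed after dialect stripping."""

    def __init__(self, message: str, offset: int | None = None):
        super().__init__(message)
        self.offset = offset


class EmptyDatabaseError(SoilmatchError):
    """The database holds no records (k >= 1 is required)."""


class DimensionError(SoilmatchError):
    """Feature vectors of unequal length were compared."""
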
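"""Exception hierarchy for the guildflux pipeline."""


class GuildfluxError(Exception):
    """Base class for all pipeline errors."""


class InvalidInputError(GuildfluxError):
    """A physical quantity or measurement is out of its valid domain."""


class DegenerateDesignError(GuildfluxError):
    """Too few distinct design points to fit the requested model."""


class IncompleteDesignError(GuildfluxError):
    """A mandatory treatment slope is missing from a partition design."""


class UndefinedRatioError(GuildfluxError):
    """The IAR denominator (control minus combined) vanishes."""


class InsufficientPairsError(GuildfluxError):
    """Fewer paired observations than a paired test requires."""


class NoSignalError(GuildfluxError):
    """Every site's total activity falls below the reporting floor."""


class InvalidConfigError(GuildfluxError):
    """A synthetic or run configuration violates its invariants."""


class SchemaError(GuildfluxError):
    """An input table violates the expected schema; carries row context."""
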
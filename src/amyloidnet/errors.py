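"""Exception hierarchy shared across the pipeline stages."""


class AmyloidNetError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AmyloidNetError):
    """A fixture file could not be parsed in its declared dialect."""


class SchemaError(AmyloidNetError):
    """An input table is missing a required column."""


class ValidationError(AmyloidNetError):
    """A record violates a domain constraint (bad role, score range, id)."""


class ConsistencyError(AmyloidNetError):
    """Inputs contradict each other (category clash, asymmetric matrix)."""


class UndefinedInputError(AmyloidNetError):
    """The requested statistic is undefined on this input (e.g. N < 2)."""


class DegenerateFitError(AmyloidNetError):
    """The degree sequence cannot support a power-law fit."""


class InfeasibleError(AmyloidNetError):
    """A requested construction is impossible (too many edges, pool exhausted)."""
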
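"""Exception hierarchy for pestcast."""


class PestcastError(Exception):
    """Base class for all pestcast errors."""


class InvalidArgumentError(PestcastError, ValueError):
    """An argument violates a documented precondition."""


class ConfigurationError(PestcastError):
    """A configuration object is incomplete or inconsistent."""


class DataError(PestcastError):
    """Input data violates an invariant (non-finite values, bad dtypes...)."""


class SchemaError(DataError):
    """A tabular input is missing a required column."""


class DegenerateInputError(PestcastError, ValueError):
    """The input is too degenerate for the operation (e.g. fewer distinct
    values than clusters)."""


class InsufficientDataError(PestcastError, ValueError):
    """Not enough records to perform the operation."""


class DegenerateLabelsError(PestcastError, ValueError):
    """Training labels contain a single class."""


class UndefinedMetricError(PestcastError, ValueError):
    """A metric is undefined for the given input (e.g. AUC with one class)."""


class InternalError(PestcastError):
    """An internal consistency check failed; indicates a bug."""
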
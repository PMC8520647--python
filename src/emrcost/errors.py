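"""Exception hierarchy for the emrcost package."""


class EmrCostError(Exception):
    """Base class for all package errors."""


class ConfigError(EmrCostError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class SchemaError(EmrCostError, KeyError):
    """A record column that the schema does not declare."""


class VocabularyError(EmrCostError, ValueError):
    """A text value outside a column's declared vocabulary."""


class DomainError(EmrCostError, ValueError):
    """An argument outside the mathematical domain of an operation."""


class ParseError(EmrCostError, ValueError):
    """A malformed CSV row; the message carries the line number."""


class ImputationError(EmrCostError, ValueError):
    """Imputation cannot proceed (too few donors, or no shared features)."""


class UndefinedCPTError(EmrCostError, ValueError):
    """A conditional probability is undefined (unseen parent configuration
    with zero smoothing)."""
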
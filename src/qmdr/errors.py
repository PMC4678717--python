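"""Exception hierarchy shared across the package."""


class QmdrError(Exception):
    """Base class for all package errors."""


class ParseError(QmdrError):
    """A file could not be parsed under the named standard."""


class DimensionError(QmdrError):
    """Inconsistent row/column counts in an input file."""


class UndefinedValueError(QmdrError):
    """A statistic is undefined on the given input (e.g. all-missing column)."""


class InsufficientDataError(QmdrError):
    """Too few observations to compute the requested estimate."""


class EmptyResultError(QmdrError):
    """A filter stage removed everything; names the offending filter."""


class CollinearityError(QmdrError):
    """Rank-deficient regression design; lists the dependent columns."""


class DegenerateModelError(QmdrError):
    """A model cannot be evaluated (e.g. all individuals missing a genotype)."""


class MappingError(QmdrError):
    """Requested SNPs/genes are absent from the dataset."""


class ConfigError(QmdrError):
    """Invalid pipeline configuration."""
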
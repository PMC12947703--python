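"""Exception hierarchy shared across the package."""


class RiceWueError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(RiceWueError):
    """A required column or field is missing from an input file."""


class ParseError(RiceWueError):
    """A value in an input file could not be parsed."""


class IntegrityError(RiceWueError):
    """Input violates a structural invariant (duplicate keys, bad ordering)."""


class ConfigError(RiceWueError):
    """A configuration object is internally inconsistent."""


class DegenerateDataError(RiceWueError):
    """Data have no usable variation (zero variance, constant trait, ...)."""


class UnbalancedDesignError(RiceWueError):
    """A balanced factorial design was required but the data are unbalanced."""
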
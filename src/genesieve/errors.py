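"""Exception hierarchy shared across the package."""


class GenesieveError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(GenesieveError):
    """A run was configured inconsistently (missing column, bad option)."""


class ParseError(GenesieveError):
    """An input file could not be interpreted; message names the offending cell."""


class ValidationError(GenesieveError):
    """Data violated a structural invariant (class sizes, shapes, uniqueness)."""


class ContractError(GenesieveError):
    """A function was called with arguments outside its documented contract."""
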
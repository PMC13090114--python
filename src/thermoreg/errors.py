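"""Exception hierarchy shared across the package.

Exit codes follow the CLI contract: 2 for data problems, 3 for
configuration problems.
"""


class ThermoregError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class DataError(ThermoregError):
    """Input data violates an invariant (bad values, empty input, ...)."""

    exit_code = 2


class ParseError(DataError):
    """A file could not be parsed; the message names the offending row."""


class ConfigError(ThermoregError):
    """A configuration value is inconsistent or out of range."""

    exit_code = 3


class UndefinedEfficiencyError(DataError):
    """Hertz index is undefined: mean operative deviation is exactly zero.

    This is the degenerate "perfect habitat" case in which every available
    operative temperature already lies inside the set-point range, so
    E = 1 - db/de has no meaning.  It is reported explicitly rather than
    silently clipped.
    """
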
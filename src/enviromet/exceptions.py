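"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ConfigError -> 2, DataError -> 3,
ConvergenceError -> 4.
"""


class EnviroMetError(Exception):
    """Base class for all package errors."""


class ConfigError(EnviroMetError):
    """Invalid configuration (bad dimensions, missing settings, bad thresholds)."""


class DataError(EnviroMetError):
    """Invalid or inconsistent input data (missing columns, empty tables, mismatched ids)."""


class ConvergenceError(EnviroMetError):
    """A model fit failed to converge and the caller required convergence."""
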
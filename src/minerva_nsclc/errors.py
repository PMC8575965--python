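"""Exception hierarchy shared across the package.

Each CLI-facing class maps to a distinct process exit code so shell callers
can distinguish schema problems from statistical degeneracies from I/O.
"""


class MinervaError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class SchemaError(MinervaError):
    """Malformed input table: missing column, bad enum value, duplicate id."""

    exit_code = 2


class ParseError(SchemaError):
    """Row-level parse failure (carries the offending row index)."""

    def __init__(self, message: str, row: int | None = None):
        super().__init__(message if row is None else f"row {row}: {message}")
        self.row = row


class ConfigError(MinervaError):
    """Invalid configuration (cutoffs, fold counts, missing weight artifact)."""

    exit_code = 2


class DegenerateDataError(MinervaError):
    """Statistically unusable input: zero events, empty group, constant score."""

    exit_code = 3


class ConvergenceError(DegenerateDataError):
    """Monotone partial likelihood / perfect separation; names the covariate."""

    def __init__(self, message: str, covariate: str | None = None):
        super().__init__(message)
        self.covariate = covariate
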
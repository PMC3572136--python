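"""Exception types shared across the pipeline."""


class CretoolsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CretoolsError):
    """Invalid configuration: missing columns, unknown labels, bad thresholds."""


class StatementParseError(CretoolsError):
    """A causal-statement row could not be parsed.

    Carries the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


class ContractViolation(CretoolsError):
    """Caller broke a documented precondition (inconsistent margins, misaligned inputs)."""


class InsufficientReplication(CretoolsError):
    """A statistical test was requested with fewer than two replicates per group."""


class UndefinedFraction(CretoolsError):
    """A fraction was requested with an empty or zero denominator."""
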
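"""Exception types shared across the package."""


class ValidationError(ValueError):
    """A value violates a domain invariant (range, sign, consistency)."""


class ConfigurationError(ValueError):
    """A cohort/pipeline configuration is invalid; names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"invalid configuration field '{field}': {message}")


class SchemaError(ValueError):
    """A cohort file's columns do not match the expected schema."""


class CohortParseError(ValueError):
    """A cohort file row could not be parsed; carries the 1-based line number."""

    def __init__(self, line: int, message: str):
        self.line = line
        super().__init__(f"line {line}: {message}")


class SeparationError(RuntimeError):
    """Logistic fit failed to converge, consistent with (quasi-)separation."""
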
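"""Exception hierarchy shared across the package."""


class CoannoQCError(Exception):
    """Base class for all errors raised by this package."""


class OboParseError(CoannoQCError):
    """Malformed OBO input (bad CURIE, dangling edge target, ...)."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class UnknownTermError(CoannoQCError, KeyError):
    """A term id that resolves neither as a primary id nor as an alt_id."""

    def __str__(self) -> str:  # KeyError quotes its arg; we want a sentence
        return self.args[0] if self.args else ""


class ObsoleteTermError(CoannoQCError):
    """Traversal was requested from an obsolete term without redirection."""


class OntologyCycleError(CoannoQCError):
    """A cycle among traversable edges; the message names one cycle."""


class GafParseError(CoannoQCError):
    """Malformed GAF record in strict mode."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class RuleParseError(CoannoQCError):
    """Malformed co-annotation rule line."""

    def __init__(self, message: str, line_no: int | None = None):
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)
        self.line_no = line_no


class ConfigError(CoannoQCError):
    """Contradictory or invalid configuration (e.g. an evidence code both
    included and excluded)."""


class FixtureError(CoannoQCError):
    """Infeasible synthetic-fixture specification."""
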
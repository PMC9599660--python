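"""Exception hierarchy shared across the toolkit."""


class EcModelKitError(Exception):
    """Base class for all toolkit errors."""


class InvalidIdentifierError(EcModelKitError):
    """An identifier is empty or otherwise unusable."""


class FormatError(EcModelKitError):
    """A model file could not be parsed under the named standard."""


class ValidationError(EcModelKitError):
    """A model document violates its structural invariants.

    ``problems`` lists every offending item, so callers can report all
    defects at once rather than fixing them one by one.
    """

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("model validation failed:\n" + "\n".join(f"  - {p}" for p in self.problems))


class GprParseError(EcModelKitError):
    """A gene-protein-reaction rule is not a well-formed boolean expression."""

    def __init__(self, message, position=None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class SolverError(EcModelKitError):
    """The linear-programming solver failed or reported a non-optimal status."""
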
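"""Exception hierarchy.

Error classes are split along the CLI exit-code contract: schema / I-O
problems (exit 2) versus semantic failures of the definitional clauses
(exit 1).
"""


class ContsemError(Exception):
    """Base class for all package errors."""


class SchemaError(ContsemError):
    """A document violates the JSON schema; carries a JSON-pointer-ish path."""

    def __init__(self, path: str, message: str):
        self.path = path
        super().__init__(f"{path}: {message}")


class ExactnessError(SchemaError):
    """A decimal literal was found where exact rational input is required."""


class ResolutionError(ContsemError):
    """A referenced identifier does not resolve within the document."""


class StructuralError(ContsemError):
    """A structural invariant is violated (interval order, subevent cycle,
    containment, null life-time, ...)."""


class InjectionError(ContsemError):
    """An anomaly injection was requested at an invalid location."""


class InvariantViolation(ContsemError):
    """An internal consistency check failed (e.g. a delay episode outside
    the event's temporal extent)."""
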
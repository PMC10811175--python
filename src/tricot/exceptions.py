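"""Exception hierarchy for the tricot toolkit.

The CLI maps :class:`ValidationError` subclasses to exit code 2 and
:class:`ModelError` subclasses to exit code 3.
"""


class TricotError(Exception):
    """Base class for all package errors."""


class ValidationError(TricotError):
    """Invalid input data or configuration."""


class SchemaError(ValidationError):
    """A file does not match its documented schema."""


class InvalidResponseError(ValidationError):
    """A farmer response is internally contradictory (e.g. best == worst)."""


class DuplicateRecordError(ValidationError):
    """Two records share a (participant, trait) key."""


class DisconnectedError(ValidationError):
    """The item comparison graph is not connected; worths are not identifiable."""

    def __init__(self, components):
        self.components = [sorted(c) for c in components]
        parts = "; ".join("{" + ", ".join(c) + "}" for c in self.components)
        super().__init__(
            f"comparison graph has {len(self.components)} connected components: {parts}"
        )


class ModelError(TricotError):
    """Model estimation failed."""


class ConvergenceError(ModelError):
    """An iterative fit did not converge within its iteration budget."""
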
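"""Exception hierarchy for vitrodist."""


class VitrodistError(Exception):
    """Base class for all package errors."""


class ValidationError(VitrodistError):
    """A record violates a structural invariant (bad field value, inconsistent class)."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class ParameterizationError(VitrodistError):
    """A model flavor requires a chemical parameter that is absent."""


class ApplicabilityError(VitrodistError):
    """A model flavor was applied outside its chemical applicability domain."""


class SchemaError(VitrodistError):
    """An input table is missing columns or contains unparseable cells."""
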
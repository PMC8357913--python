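"""Exception hierarchy shared across the package."""


class ProxiquantError(Exception):
    """Base class for all package errors."""


class SchemaError(ProxiquantError):
    """A required column or field is missing from an input table."""


class ValidationError(ProxiquantError):
    """An input violates a structural invariant (duplicates, bad ranges...)."""


class ParameterError(ProxiquantError):
    """A parameter value is outside its admissible range."""


class StageError(ProxiquantError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage {stage!r} failed: {cause}")
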
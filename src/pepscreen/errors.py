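"""Exception types shared across the package."""


class PepscreenError(Exception):
    """Base class for all package errors."""


class ParseError(PepscreenError):
    """A SMILES string could not be parsed or sanitized."""

    def __init__(self, message: str, molecule_id: str | None = None):
        self.molecule_id = molecule_id
        if molecule_id is not None:
            message = f"[{molecule_id}] {message}"
        super().__init__(message)


class ConfigurationError(PepscreenError):
    """Invalid rule name, variant, or parameter value."""


class MissingDescriptorError(PepscreenError):
    """A rule references a descriptor that is absent from the input."""


class FeatureLayoutError(PepscreenError):
    """Prediction input does not match the feature layout a model was trained on."""


class IntegrityError(PepscreenError):
    """A persisted model artifact and its metadata sidecar disagree."""
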
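"""Exception hierarchy shared across the pipeline."""


class AccModeError(Exception):
    """Base class for all errors raised by this package."""


class FormatError(AccModeError):
    """A file violates the expected CSV/GeoJSON structure."""


class ParseError(FormatError):
    """A cell could not be parsed as the expected type."""


class FeatureError(AccModeError):
    """Invalid feature selection or feature-table mismatch."""


class ModelError(AccModeError):
    """Invalid training input or model configuration."""


class BundleLoadError(ModelError):
    """A persisted model bundle is corrupt or incompatible."""


class EvaluationError(AccModeError):
    """Invalid cross-validation setup or degenerate evaluation input."""
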
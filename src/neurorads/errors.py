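"""Exception hierarchy shared across the pipeline."""


class NeuroradsError(Exception):
    """Base class for all package errors."""


class InvalidParameterError(NeuroradsError, ValueError):
    """A configuration value or function argument is out of its valid range."""


class InvalidInputError(NeuroradsError, ValueError):
    """Input data violate a precondition (NaN voxels, empty required mask...)."""


class GeometryError(NeuroradsError, ValueError):
    """Two volumes that must share a grid do not (shape/spacing/orientation)."""


class EmptyMaskError(InvalidInputError):
    """An operation that requires foreground voxels received an empty mask."""


class RegistrationError(NeuroradsError, RuntimeError):
    """Transform estimation failed (degenerate moving image, singular matrix)."""


class PredictorContractError(NeuroradsError, RuntimeError):
    """A plugged-in predictor broke its contract (shape or range violation)."""


class ConfigError(NeuroradsError, ValueError):
    """Run configuration is inconsistent (non-monotone thresholds, bad schema)."""
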
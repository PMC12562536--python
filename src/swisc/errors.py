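"""Exception hierarchy for the swisc pipeline."""


class SwiscError(Exception):
    """Base class for all pipeline errors."""


class LayoutError(SwiscError):
    """Channel layout does not provide the required roles."""


class DataQualityError(SwiscError):
    """Signal contains NaN/Inf or otherwise uninterpretable values."""


class DegenerateChannelError(DataQualityError):
    """Channel has zero variance and cannot be normalized."""


class DegenerateEpochError(SwiscError):
    """Epoch carries no broadband spectral power."""


class ConfigError(SwiscError):
    """Invalid configuration value."""


class FormatError(SwiscError):
    """Malformed on-disk artifact (gaps, shape mismatch, bad sidecar)."""


class VocabularyError(FormatError):
    """Label outside the five-state alphabet."""


class LeakageError(SwiscError):
    """A subject appears in more than one dataset partition."""


class CompatibilityError(SwiscError):
    """Feature manifest does not match the one the model was trained on."""


class DivergenceError(SwiscError):
    """Training produced a non-finite loss."""
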
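"""Exception hierarchy for the short-term-plasticity pipeline."""


class STPError(Exception):
    """Base class for all package errors."""


class ParameterDomainError(STPError, ValueError):
    """A characteristic parameter lies outside its admissible domain."""


class ProtocolError(STPError, ValueError):
    """A pulse protocol is ill-formed (no pulses, negative width, ...)."""


class ResolutionError(STPError, ValueError):
    """Trace sampling is too coarse to resolve the pulse structure."""


class ExtractionError(STPError, ValueError):
    """Peak extraction failed; carries the offending pulse indices."""

    def __init__(self, message: str, pulse_indices: list[int] | None = None):
        super().__init__(message)
        self.pulse_indices = pulse_indices or []


class NormalizationError(STPError, ValueError):
    """Peak sequence cannot be normalized (non-positive baseline peak)."""


class InferenceError(STPError, RuntimeError):
    """Parameter inference failed or is underdetermined."""


class ConfigError(STPError, ValueError):
    """Pipeline configuration is invalid; carries the offending keys."""

    def __init__(self, message: str, keys: list[str] | None = None):
        super().__init__(message)
        self.keys = keys or []
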
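"""Exception types shared across the pipeline."""


class ConfigError(ValueError):
    """Invalid configuration value (non-positive sizes, bad rates, unknown tags)."""


class DegenerateSampleError(ValueError):
    """Sample has zero variance; scale-based estimators are undefined."""


class SelectorNumericError(RuntimeError):
    """A bandwidth-selector stage produced a non-finite or wrong-signed functional."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class AlignmentError(ValueError):
    """Replicate indices of two series do not match."""


class ScvBoundaryWarning(UserWarning):
    """SCV criterion had no interior minimum inside the search bracket."""
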
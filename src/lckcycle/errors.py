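"""Exception types shared across the toolkit."""


class LckCycleError(Exception):
    """Base class for all toolkit errors."""


class ConfigError(LckCycleError, ValueError):
    """Invalid configuration or generator specification."""


class EmptyInputError(LckCycleError, ValueError):
    """An input table, file or mask was empty where data was required."""


class DemultiplexError(LckCycleError, RuntimeError):
    """Barcode populations could not be resolved; carries diagnostics."""

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class SegmentationError(LckCycleError, RuntimeError):
    """ROI segmentation failed (blank channel, empty compartment...)."""


class FitError(LckCycleError, RuntimeError):
    """A regression or grid fit could not be performed."""
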
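"""Exception hierarchy shared across the package."""


class PumpProbeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(PumpProbeError, ValueError):
    """Invalid configuration value (unknown layout, bad bounds, ...)."""


class MissingFrameError(PumpProbeError, ValueError):
    """A required delay frame is absent from the stack."""


class FormatError(PumpProbeError, ValueError):
    """A file on disk violates the stack/sidecar format contract."""
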
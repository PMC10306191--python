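"""Exception hierarchy shared across the package."""


class RsvpSimError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(RsvpSimError, ValueError):
    """Invalid parameter or configuration value."""


class ShapeError(RsvpSimError, ValueError):
    """Structurally incompatible array shapes or lengths."""


class DegenerateInputError(RsvpSimError, ValueError):
    """Input is formally valid but carries no usable signal
    (e.g. zero-variance reference, all-undefined trace)."""
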
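"""Exception hierarchy shared across the package."""


class ALCSError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ALCSError, ValueError):
    """A parameter violates its physical or mathematical constraints."""


class InsufficientDataError(ALCSError, ValueError):
    """Too few usable data points for the requested estimate."""


class NoSelectionPossibleError(ALCSError, ValueError):
    """Transformed cells do not outgrow non-transformed cells (mu1 <= mu2, k >= 1)."""


class LayoutError(ALCSError, ValueError):
    """A plate layout request exceeds the plate capacity."""


class ConfigError(ALCSError, ValueError):
    """A run configuration file is missing, unparseable, or invalid."""
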
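"""Exception hierarchy shared across the toolkit."""


class HypyieldError(Exception):
    """Base class for all toolkit errors."""


class ConfigurationError(HypyieldError, ValueError):
    """An invalid parameter set (bad window sizes, degenerate ranges, ...)."""


class FormatError(HypyieldError, ValueError):
    """A file does not conform to its declared on-disk format."""


class DimensionError(HypyieldError, ValueError):
    """Array shapes or feature layouts do not agree."""


class DataError(HypyieldError, ValueError):
    """Input values are unusable (non-finite, zero variance, empty ROI, ...)."""
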
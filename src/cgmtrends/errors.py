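"""Exception hierarchy shared across the package."""


class CgmTrendsError(Exception):
    """Base class for package-specific errors."""


class TrendParseError(CgmTrendsError, ValueError):
    """An arrow token could not be mapped to a trend category."""


class ProfileMismatchError(CgmTrendsError, ValueError):
    """Two trend categories from different device profiles were combined."""


class TraceRangeError(CgmTrendsError, ValueError):
    """Interpolation requested outside the span of a glucose trace."""


class TraceGapError(CgmTrendsError, ValueError):
    """The bracketing samples around the requested time are too far apart."""


class SchemaError(CgmTrendsError, ValueError):
    """An input file does not conform to the expected column layout."""


class ConfigurationError(CgmTrendsError, ValueError):
    """The study inputs are inconsistent (e.g. a diary sensor without a trace)."""
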
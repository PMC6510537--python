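"""Exception hierarchy for tifquant.

Every error raised on purpose by the package derives from TifquantError so
callers (and the CLI) can distinguish user/data problems from bugs.
"""


class TifquantError(Exception):
    """Base class for all tifquant errors."""


class SchemaError(TifquantError):
    """A required column or field is absent or malformed."""


class ValidationError(TifquantError):
    """Data violate an invariant (duplicates, negative areas, non-monotone levels...)."""


class CrossReferenceError(TifquantError):
    """A record refers to an entity that does not exist (e.g. unknown sample_id)."""


class ConfigError(TifquantError):
    """A configuration value is out of range or inconsistent."""


class CalibrationError(TifquantError):
    """Calibration cannot be performed (no usable levels, degenerate curve...)."""


class AssemblyError(TifquantError):
    """Partial concentration tables overlap or cannot be merged."""
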
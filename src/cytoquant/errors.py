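"""Exception hierarchy for cytoquant.

All user-facing errors derive from :class:`CytoquantError` so callers can
catch one base class at pipeline boundaries.
"""


class CytoquantError(Exception):
    """Base class for all cytoquant errors."""


class SchemaError(CytoquantError):
    """An input table is missing required columns or has the wrong dtypes."""


class ValidationError(CytoquantError):
    """An input violates a structural invariant (e.g. non-monotone time)."""


class ConfigError(CytoquantError):
    """A configuration file contains unknown keys or invalid values."""


class ParameterError(CytoquantError):
    """A function argument is outside its valid domain."""


class DegenerateTraceError(CytoquantError):
    """A trace is constant, so min-max normalization is undefined."""
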
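"""Exception hierarchy.

``ValidationError`` flags bad data (malformed rows, impossible values),
``ConfigurationError`` flags bad settings (missing columns, cyclic synonym
maps), ``DegenerateInputError`` flags statistically degenerate inputs
(e.g. zero-variance differences in a paired test).
"""


class LepisurveyError(Exception):
    """Base class for all package errors."""


class ValidationError(LepisurveyError):
    """Input data violates an invariant."""


class ConfigurationError(LepisurveyError):
    """A configuration value or mapping is unusable."""


class DegenerateInputError(LepisurveyError):
    """Statistically degenerate input (a test statistic is undefined)."""
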
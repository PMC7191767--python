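"""Exception hierarchy.

All generator errors derive from :class:`SurvgenError` so callers (and the
CLI) can catch one base class; ``ParameterError`` flags a value outside a
mathematical domain, ``ConfigurationError`` flags an inconsistent or
infeasible configuration, ``NoValidCutoffError`` flags a dichotomization
request with no admissible cutpoint.
"""


class SurvgenError(ValueError):
    """Base class for all errors raised by this package."""


class ParameterError(SurvgenError):
    """A parameter violates its mathematical domain (e.g. shape <= 0)."""


class ConfigurationError(SurvgenError):
    """A configuration is internally inconsistent or infeasible."""


class NoValidCutoffError(SurvgenError):
    """No cutoff satisfies the dichotomization constraints."""
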
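"""Exception hierarchy.

``InputError`` flags bad data (negative concentrations, unknown category
literals, malformed CSV); ``ConfigError`` flags inconsistent configuration
(non-monotone cutoffs, non-contiguous merge groups, incomplete risk
matrices); ``UndefinedKappaError`` flags degenerate agreement tables whose
chance agreement is 1, for which Cohen's kappa has no value.
"""


class UrisedError(Exception):
    """Base class for all errors raised by this package."""


class InputError(UrisedError, ValueError):
    """Invalid input data."""


class ConfigError(UrisedError, ValueError):
    """Invalid or inconsistent configuration."""


class UndefinedKappaError(UrisedError):
    """Kappa is undefined because expected chance agreement equals 1.

    This happens when both raters use a single identical category for every
    sample (e.g. a parameter that is negative in the whole cohort), so there
    is no chance-corrected information in the table.
    """
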
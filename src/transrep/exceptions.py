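"""Exception hierarchy for transrep.

All package errors derive from :class:`TransrepError` so callers can catch
one base class; the CLI maps subclasses to distinct exit codes.
"""


class TransrepError(Exception):
    """Base class for all transrep errors."""


class FormatError(TransrepError):
    """A file does not conform to the expected tabular layout."""


class ValidationError(TransrepError):
    """Field-level content is invalid (bad allele, duplicate rsid, ...)."""


class ParameterError(TransrepError):
    """A numeric argument is outside its admissible range."""


class DataError(TransrepError):
    """The data cannot support the requested computation (empty stratum,
    insufficient pool, degenerate score distribution, ...)."""


class RankError(TransrepError):
    """Design matrix is rank deficient; message names collinear columns."""


class SeparationError(TransrepError):
    """Complete or quasi-complete separation in a logistic fit."""
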
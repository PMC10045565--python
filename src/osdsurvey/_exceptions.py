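"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ParameterError / ValidationError -> 2,
DegenerateDataError -> 3.
"""


class OsdSurveyError(Exception):
    """Base class for all package errors."""


class ParameterError(OsdSurveyError, ValueError):
    """A configuration or function parameter is invalid; names the field."""


class ValidationError(OsdSurveyError, ValueError):
    """Input data failed validation; carries per-row detail where available.

    Parameters
    ----------
    message : str
    errors : list of (row, column, detail) tuples, optional
    """

    def __init__(self, message, errors=None):
        super().__init__(message)
        self.errors = list(errors) if errors else []


class DegenerateDataError(OsdSurveyError, ValueError):
    """The data admit no well-defined answer (zero variance, empty class...)."""
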
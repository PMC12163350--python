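"""Exception hierarchy shared across the pipeline stages."""


class FacsurveyError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FacsurveyError):
    """A configuration document or parameter set is invalid.

    The message names the offending field. Mapped to exit code 2 by the CLI.
    """


class DataError(FacsurveyError):
    """Input data violate a stage precondition (duplicates, bad weights, ...).

    Mapped to exit code 1 by the CLI.
    """
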
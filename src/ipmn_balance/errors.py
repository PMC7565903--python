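"""Exception hierarchy shared across the package."""


class IpmnBalanceError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IpmnBalanceError, ValueError):
    """A generative or model configuration is invalid.

    The message always names the offending field so that YAML/JSON configs
    can be fixed line by line.
    """


class MissingDataError(IpmnBalanceError, ValueError):
    """A record lacks a feature required by a model.

    Records with incomplete data are excluded from scoring rather than
    imputed; the caller decides how to handle them.
    """


class CohortValidationError(IpmnBalanceError, ValueError):
    """A cohort file failed validation; the message cites the row."""
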
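"""Exception types shared across the package."""


class LipidsimError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(LipidsimError, ValueError):
    """A configuration object violates its invariants.

    Carries the full list of violations so a user can fix a config file in
    one pass rather than one key at a time.
    """

    def __init__(self, errors):
        if isinstance(errors, str):
            errors = [errors]
        self.errors = list(errors)
        super().__init__("; ".join(self.errors))


class SchemaError(LipidsimError, ValueError):
    """A tabular input is missing a mandatory column."""


class ParseError(LipidsimError, ValueError):
    """A tabular input contains an unparseable value; message names the row."""


class MissingCovariateError(LipidsimError, ValueError):
    """A risk equation was called on a patient lacking a required covariate."""


class DomainError(LipidsimError, ValueError):
    """A numeric argument is outside the mathematical domain of an operation."""
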
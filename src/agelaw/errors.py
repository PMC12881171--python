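"""Exception types shared across the package."""


class AgelawError(Exception):
    """Base class for all package-specific errors."""


class ParseError(AgelawError):
    """A CSV row could not be parsed or violates a record invariant."""


class DomainError(AgelawError, ValueError):
    """An input lies outside the mathematical domain of an operation."""


class UnderdeterminedError(AgelawError):
    """Fewer data points than the model requires."""


class IncompatibleGridError(AgelawError):
    """Registry series do not share an identical age-bin grid."""


class MissingWeightsError(AgelawError):
    """Pooling requested without case counts and without a fallback."""


class CollinearPredictorsError(AgelawError):
    """The two competing predictors are numerically indistinguishable."""


class ConfigError(AgelawError):
    """Invalid analysis configuration; carries the full list of problems."""

    def __init__(self, problems):
        self.problems = list(problems)
        super().__init__("; ".join(self.problems))
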
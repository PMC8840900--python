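"""Exception hierarchy: configuration, data, state, numeric, and fit errors."""


class ForestBirdError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ForestBirdError):
    """Invalid configuration: missing columns, bad option values, impossible requests."""


class DataError(ForestBirdError):
    """Input data violates a precondition (zero variance, missing months, ...)."""


class StateError(ForestBirdError):
    """Operation applied in the wrong pipeline state (e.g. doubling pair counts twice)."""


class SpeciesLookupError(ForestBirdError):
    """Species codes present in counts but absent from the trait table."""

    def __init__(self, codes):
        self.codes = sorted(codes)
        super().__init__(f"species codes missing from trait table: {', '.join(self.codes)}")


class NumericError(ForestBirdError):
    """Numerical failure: non-finite values, non-positive-definite matrices."""


class FitError(ForestBirdError):
    """Model fitting failed beyond recoverable non-convergence."""


class ComparisonError(ForestBirdError):
    """Model comparison attempted across different data sets."""
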
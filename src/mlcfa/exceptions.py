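"""Exception hierarchy for mlcfa."""


class MlcfaError(Exception):
    """Base class for all mlcfa errors."""


class ConfigurationError(MlcfaError):
    """Missing columns, unknown labels, malformed config."""


class ParseError(MlcfaError):
    """Non-numeric cell or unreadable input file."""


class ValidationError(MlcfaError):
    """Dataset violates a structural invariant (e.g. fewer than 2 clusters)."""


class NotPositiveDefiniteError(MlcfaError):
    """A covariance matrix required to be positive definite is not.

    Carries the offending smallest eigenvalue in ``min_eigenvalue``.
    """

    def __init__(self, message: str, min_eigenvalue: float | None = None):
        super().__init__(message)
        self.min_eigenvalue = min_eigenvalue


class UnidentifiableModelError(MlcfaError):
    """Free parameters exceed fitted moments (df < 0)."""
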
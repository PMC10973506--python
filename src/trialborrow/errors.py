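"""Exception types shared across the package."""


class TrialBorrowError(Exception):
    """Base class for package errors."""


class ConfigError(TrialBorrowError, ValueError):
    """Invalid configuration (non-positive counts/rates, bad probabilities...)."""


class DataValidationError(TrialBorrowError, ValueError):
    """A dataset violates the patient-record schema or its invariants."""


class MilestoneError(TrialBorrowError, ValueError):
    """An interim milestone is infeasible for the available data."""


class SeparationError(TrialBorrowError, RuntimeError):
    """Complete separation in the propensity logistic regression.

    Carries a human-readable diagnostic in ``args[0]``.
    """


class ConvergenceError(TrialBorrowError, RuntimeError):
    """A deterministic numerical routine (optimiser, root search) failed."""
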
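"""Exception types shared across the package."""


class MRSuiteError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(MRSuiteError, ValueError):
    """A simulation or analysis configuration is internally inconsistent."""


class DegenerateInputError(MRSuiteError, ValueError):
    """Input data admit no meaningful result (constant vector, empty set, ...)."""


class AlignmentError(MRSuiteError, ValueError):
    """Genotype dosages cannot be reconciled with a weights table."""


class EstimationError(MRSuiteError, RuntimeError):
    """A model fit failed (separation, rank deficiency, no variance)."""


class InsufficientDataError(MRSuiteError, ValueError):
    """Too few observations/variants for the requested estimator."""


class WeakInstrumentWarning(UserWarning):
    """First-stage F statistic below the configured floor."""
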
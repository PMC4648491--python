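"""Exception and warning hierarchy shared across the package."""


class SmartDdpcrError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(SmartDdpcrError, ValueError):
    """Malformed or out-of-contract input (bad counts, missing columns, ...)."""


class SaturationError(SmartDdpcrError, ValueError):
    """All droplets positive: the Poisson estimate of concentration is unbounded."""


class UndefinedProportionError(SmartDdpcrError, ZeroDivisionError):
    """Both allele concentrations are zero; the allele proportion is undefined."""


class InsufficientCalibrationError(SmartDdpcrError, ValueError):
    """Fewer than two constitutional measurements: no SD, no thresholds."""


class UndefinedTestError(SmartDdpcrError, ValueError):
    """No samples with allelic imbalance; the binomial test has n = 0."""


class DegenerateThresholdsWarning(UserWarning):
    """Constitutional SD is zero; upper and lower thresholds coincide."""


class UnmappedTraitWarning(UserWarning):
    """A GWAS trait phrase was absent from the cancer-type vocabulary."""
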
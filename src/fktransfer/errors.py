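"""Exception types shared across the pipeline."""


class FktError(Exception):
    """Base class for all package errors."""


class MissingGeneError(FktError, KeyError):
    """A gene id was not found in the container it was looked up in."""


class InsufficientDataError(FktError):
    """Too few observations to compute a score (e.g. <2 overlapping conditions)."""


class ConfigurationError(FktError):
    """Invalid or inconsistent configuration."""


class EvidenceError(FktError):
    """Malformed evidence value; message carries dataset/pair context."""


class UndefinedMIError(FktError):
    """Mutual information undefined (empty joint support)."""


class CalibrationError(FktError):
    """Sigmoid calibration could not be fitted (degenerate scores)."""


class UntrainableTermError(FktError):
    """A term has no positive examples and cannot be trained."""
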
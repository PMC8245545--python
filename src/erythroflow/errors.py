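"""Exception hierarchy for the erythroflow pipeline."""


class ErythroflowError(Exception):
    """Base class for all package errors."""


class ConfigurationError(ErythroflowError, ValueError):
    """Invalid generator or pipeline configuration."""


class FormatError(ErythroflowError, IOError):
    """Unreadable, inconsistent or unsupported video/ROI container."""


class EstimationError(ErythroflowError, RuntimeError):
    """A signal-derived quantity (e.g. the barrier column) could not be estimated."""


class BackendUnavailableError(ErythroflowError, RuntimeError):
    """A feature backend cannot run in this installation (e.g. missing CNN weights)."""


class SelectionError(ErythroflowError, ValueError):
    """Feature selection cannot produce a valid mask."""


class TrainingError(ErythroflowError, ValueError):
    """Classifier training preconditions violated (e.g. a single-class fold)."""


class DecisionError(ErythroflowError, ValueError):
    """A video-level decision could not be made (e.g. no predictions for a video)."""
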
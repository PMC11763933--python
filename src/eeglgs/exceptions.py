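"""Exception hierarchy shared by all pipeline stages."""


class EEGLGSError(Exception):
    """Base class for all package errors."""


class FormatError(EEGLGSError):
    """A file could not be parsed in its declared format."""


class UnsupportedInputError(EEGLGSError):
    """Input is syntactically valid but violates a pipeline precondition."""


class InsufficientLengthError(EEGLGSError):
    """Recording too short for the requested segmentation."""


class ConfigurationError(EEGLGSError):
    """A configuration value is inconsistent (e.g. band edge above Nyquist)."""


class DegenerateSignalError(EEGLGSError):
    """A channel is constant or otherwise unusable for model fitting."""


class ContractError(EEGLGSError):
    """An operation was called outside its documented contract."""


class StratificationError(EEGLGSError):
    """Cross-validation folds cannot be built with both classes present."""


class IncompleteFeaturesError(EEGLGSError):
    """A (subject, segment, band) cell is missing one or more operators."""
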
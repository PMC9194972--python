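"""Exception hierarchy for epidwatch."""


class EpidWatchError(Exception):
    """Base class for all epidwatch errors."""


class ParseError(EpidWatchError):
    """A file could not be parsed as a DICOM object."""


class ModalityError(EpidWatchError):
    """A DICOM file is not an RTIMAGE."""


class ValidationError(EpidWatchError):
    """An image or record violates a type invariant."""


class IdentityError(EpidWatchError):
    """Objects that must share identity (patient/plan/field) do not."""


class DegenerateFieldError(EpidWatchError):
    """ROI segmentation produced no usable high-dose, low-gradient region."""


class ZeroBaselineError(EpidWatchError):
    """A baseline pixel inside the ROI is zero; relative difference undefined."""


class ConfigError(EpidWatchError):
    """Invalid simulation or surveillance configuration."""


class UndefinedRateError(EpidWatchError):
    """Sensitivity or specificity requested with a zero denominator."""
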
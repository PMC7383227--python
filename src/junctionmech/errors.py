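"""Exception hierarchy shared across modules.

The CLI maps these onto exit codes: ConfigError -> 2, DataError -> 3,
NumericalError -> 4.
"""


class JunctionMechError(Exception):
    """Base class for all package errors."""


class ConfigError(JunctionMechError):
    """Invalid configuration or parameters."""


class DataError(JunctionMechError):
    """Invalid or inconsistent input data."""


class NumericalError(JunctionMechError):
    """A numerical procedure failed (registration, calibration, ...)."""


class RegistrationError(NumericalError):
    """Rigid drift estimation failed (no reliable correlation peak)."""


class CalibrationError(NumericalError):
    """FRET crossover calibration failed (no usable foreground)."""


class SegmentationError(NumericalError):
    """Junction segmentation produced no usable mask or cells."""


class NormalizationError(DataError):
    """Fold-of-control normalization impossible (missing control group)."""
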
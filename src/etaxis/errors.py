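"""Exception hierarchy for the etaxis package."""


class EtaxisError(Exception):
    """Base class for all package errors."""


class InvalidCalibrationError(EtaxisError):
    """A calibration field is non-positive or otherwise unusable."""


class TrackFormatError(EtaxisError):
    """A track table violates the expected CSV dialect."""


class MaskFormatError(EtaxisError):
    """A label-mask stack is not an integer image stack."""


class ConfigError(EtaxisError):
    """An invalid simulation or experiment configuration."""


class EmptyGroupError(EtaxisError):
    """A group statistic was requested on an empty collection."""


class UndefinedSpeedError(EtaxisError):
    """Speed requested for a trajectory with no elapsed time."""


class AlignmentError(EtaxisError):
    """Trajectories do not share a common frame grid."""


class SampleSizeError(EtaxisError):
    """A statistical test was given too few observations."""


class InvalidSegmentError(EtaxisError):
    """A channel segment has a non-positive dimension or property."""


class SingularNetworkError(EtaxisError):
    """The resistor network is disconnected between source terminals."""


class PlacementError(EtaxisError):
    """Ellipses could not be placed without overlap within the retry budget."""
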
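"""Exception hierarchy for boilstart.

Every failure mode the I/O and monitoring layers can hit has a distinct,
named exception so callers (and the CLI) can react to each one specifically.
"""


class BoilstartError(Exception):
    """Base class for all boilstart exceptions."""


class ConfigError(BoilstartError, ValueError):
    """An acquisition / simulation / detector configuration is inconsistent."""


class SidecarError(BoilstartError, OSError):
    """The JSON metadata sidecar of a raw acquisition is missing or invalid."""


class SampleCountError(BoilstartError, ValueError):
    """A waveform's sample count disagrees with its acquisition config."""


class NonFiniteSignalError(BoilstartError, ValueError):
    """A waveform or temperature log contains NaN or infinite values."""


class NonMonotoneTimeError(BoilstartError, ValueError):
    """Timestamps in a temperature log are not strictly increasing."""


class TemperatureNotReachedError(BoilstartError, ValueError):
    """The temperature trace never reaches the requested threshold."""


class BandRangeError(BoilstartError, ValueError):
    """A requested frequency band lies outside the available spectrum."""


class GridMismatchError(BoilstartError, ValueError):
    """Spectra to be combined do not share the same frequency grid."""


class DegenerateModelError(BoilstartError, ValueError):
    """A PCA monitoring model has no usable variance structure."""


class DetectorStateError(BoilstartError, RuntimeError):
    """The streaming detector was driven through an invalid transition."""
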
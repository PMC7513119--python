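"""Exception hierarchy for vfshock.

All errors derive from :class:`VfShockError` so callers can catch the
package's failures with one handler; each subclass maps to a distinct
contract violation (invalid sampling rate, corrupt samples, window that
cannot be cut, degenerate cohort, ...).
"""


class VfShockError(Exception):
    """Base class for all vfshock errors."""


class InvalidRateError(VfShockError, ValueError):
    """Sampling rate is non-positive or too low for the requested band."""


class DataError(VfShockError, ValueError):
    """Samples contain non-finite values or are otherwise unusable."""


class LengthError(VfShockError, ValueError):
    """Input sequence is too short for the requested operation."""


class ShapeError(VfShockError, ValueError):
    """Vector shapes are incompatible."""


class WindowError(VfShockError, ValueError):
    """A pre-shock analysis window cannot be extracted."""


class TrajectoryError(WindowError):
    """A pre-shock pause is too short to build an entropy trajectory."""


class BandError(VfShockError, ValueError):
    """Spectral analysis band is empty or inverted."""


class ClassError(VfShockError, ValueError):
    """A binary-evaluation input is missing one of the two classes."""


class FitError(VfShockError, ValueError):
    """Regression design is singular or under-determined."""


class DomainError(VfShockError, ValueError):
    """Numeric argument outside its mathematical domain."""


class SpecError(VfShockError, ValueError):
    """Synthetic cohort specification is invalid."""


class ConfigError(VfShockError, ValueError):
    """CLI/run configuration is invalid; message names the field."""
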
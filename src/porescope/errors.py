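"""Exception hierarchy.

Everything derives from :class:`PorescopeError` so callers can catch the
package's own failures without swallowing programming errors.
"""


class PorescopeError(Exception):
    """Base class for all porescope errors."""


class VolumeFormatError(PorescopeError, ValueError):
    """A density file is corrupt, truncated, or not a 3D map."""


class ParameterError(PorescopeError, ValueError):
    """An operation was given out-of-range or inconsistent parameters."""


class DegenerateOverlapError(PorescopeError, ValueError):
    """The Fourier overlap region (or score region) is empty or all-zero."""


class DegenerateDistributionError(PorescopeError, ValueError):
    """A score distribution has zero spread; Z-scores are undefined."""


class MeasurementError(PorescopeError, ValueError):
    """A geometric measurement could not be made on the given map."""


class PartitionError(PorescopeError, ValueError):
    """A half-set or class partition is empty or inconsistent."""
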
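"""Exception hierarchy.

Every failure mode the library promises to detect maps onto one of these
classes so callers (and the CLI) can distinguish user error from numerical
failure and from corrupt artifacts.
"""


class VczoneError(Exception):
    """Base class for all package errors."""


class InvalidSpecError(VczoneError, ValueError):
    """System generator parameters are inconsistent or out of range."""


class InvalidGroupError(VczoneError, ValueError):
    """An atom/bead group is empty or references invalid indices."""


class OverlapError(VczoneError, ValueError):
    """Two nonbonded beads are (numerically) coincident."""


class IntegrationError(VczoneError, RuntimeError):
    """Dynamics produced a non-finite energy or coordinate."""

    def __init__(self, message: str, step: int | None = None, run_id: int | None = None):
        super().__init__(message)
        self.step = step
        self.run_id = run_id


class SeedingError(VczoneError, RuntimeError):
    """Window-restrained seeding failed to place all runs inside the window."""


class OutOfRangeError(VczoneError, ValueError):
    """A reaction-coordinate value lies outside the zone grid's outer range."""


class InvalidGridError(VczoneError, ValueError):
    """A zone grid cannot be constructed from the given parameters."""


class StitchingError(VczoneError, RuntimeError):
    """The zone-overlap graph is disconnected; global stitching impossible."""

    def __init__(self, message: str, components=None):
        super().__init__(message)
        self.components = components or []


class EmptyEstimateError(VczoneError, RuntimeError):
    """No counts available to estimate a distribution."""


class GeometryError(VczoneError, ValueError):
    """Two grids do not share bin geometry."""


class InconsistentStoreError(VczoneError, RuntimeError):
    """A snapshot maps to a bin the histograms claim was never visited."""


class DegenerateSuperpositionError(VczoneError, ValueError):
    """Superposition selection is too small or collinear."""


class ZeroLengthVectorError(VczoneError, ValueError):
    """Head and tail group centers coincide; orientation undefined."""


class EmptyDistributionError(VczoneError, RuntimeError):
    """All weights vanished in the requested range."""


class EmptyGridError(VczoneError, RuntimeError):
    """Every sample fell outside the density grid."""


class NonNormalizableError(VczoneError, ValueError):
    """The requested Boltzmann density has no finite normalization."""


class StoreVersionError(VczoneError, RuntimeError):
    """On-disk store schema version does not match this package."""


class StoreIntegrityError(VczoneError, RuntimeError):
    """Store file is truncated or missing required payloads."""


class ExportError(VczoneError, ValueError):
    """A grid contains non-finite values and cannot be exported."""


class ConfigError(VczoneError, ValueError):
    """Run configuration failed schema validation."""
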
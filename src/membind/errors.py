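"""Package exception hierarchy."""


class MembindError(Exception):
    """Base class for all package errors."""


class InvalidCompositionError(MembindError):
    """Lipid fractions are negative or do not sum to one."""


class IntegrationInstabilityError(MembindError):
    """A dynamics step moved a particle too far relative to the interaction range."""


class DegenerateGeometryError(MembindError):
    """Bead geometry does not define an orientation (collinear/coincident beads)."""


class DisconnectedWindowsError(MembindError):
    """Umbrella windows do not form an overlapping chain along the coordinate."""


class ConvergenceError(MembindError):
    """A self-consistent iteration failed to reach tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class PoorOverlapError(MembindError):
    """Adjacent alchemical states share essentially no phase-space overlap."""


class NoWellError(MembindError):
    """A free-energy profile has no interior minimum."""


class UnknownSpeciesError(MembindError):
    """A lipid species name is not present in the bilayer."""


class InvalidTagError(MembindError):
    """The tagged lipid for an alchemical transformation is not of the expected species."""


class ScheduleMismatchError(MembindError):
    """Two alchemical legs were computed with different lambda schedules."""


class UnknownLabelError(MembindError):
    """A bead label referenced by a mask is not defined on the body."""
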
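"""Exception hierarchy for myospace."""


class MyospaceError(Exception):
    """Base class for all package errors."""


class InvalidInputError(MyospaceError, ValueError):
    """Non-finite or malformed numerical input."""


class InconsistentSystemError(MyospaceError, ValueError):
    """A linear system A x = b has no exact solution (b outside range of A).

    Attributes
    ----------
    residual : float
        Norm of the out-of-range component ``||(I - T) b||``.
    """

    def __init__(self, message: str, residual: float):
        super().__init__(message)
        self.residual = residual


class ConfigurationError(MyospaceError, ValueError):
    """Invalid model or experiment configuration; names the offending field."""


class GeometryError(MyospaceError, ValueError):
    """Degenerate muscle geometry (e.g. coincident attachment points)."""


class RankDeficiencyError(MyospaceError, ValueError):
    """A matrix required to have full rank does not."""


class KinematicSingularityError(MyospaceError, ValueError):
    """The task Jacobian (or derived operator) is singular at this posture."""


class InfeasiblePolytopeError(MyospaceError, ValueError):
    """The halfspace system Z y <= beta admits no solution."""


class UnboundedPolytopeError(MyospaceError, ValueError):
    """The halfspace system is unbounded (Z not full column rank)."""


class CapacityError(MyospaceError, ValueError):
    """The commanded action exceeds what the bounded muscles can deliver."""


class SimulationDivergedError(MyospaceError, RuntimeError):
    """Forward integration diverged (joint velocities exploded)."""
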
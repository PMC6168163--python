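"""Exception hierarchy for qORAC.

All qORAC-specific failures derive from :class:`QoracError` so callers can
catch the package's errors without masking programming mistakes.
"""


class QoracError(Exception):
    """Base class for all qORAC errors."""


class ModelError(QoracError):
    """The network definition itself is inconsistent (fatal validation)."""


class RateDomainError(QoracError):
    """A rate law was evaluated outside its domain (e.g. a pole).

    Carries the offending reaction id in ``reaction_id``.
    """

    def __init__(self, reaction_id: str, message: str | None = None):
        self.reaction_id = reaction_id
        super().__init__(message or f"rate law of reaction {reaction_id!r} "
                         "evaluated outside its domain")


class ObjectiveDomainError(QoracError):
    """The enzyme-cost objective was evaluated at a point where some
    supported reaction runs against its mode direction (f_j and V_j of
    opposite sign), so the enzyme demand V_j/f_j is meaningless there."""

    def __init__(self, reaction_id: str, message: str | None = None):
        self.reaction_id = reaction_id
        super().__init__(message or f"objective undefined: f of reaction "
                         f"{reaction_id!r} opposes the mode direction")


class OptimizationError(QoracError):
    """Interior minimisation of the enzyme-cost objective failed."""


class IFTViolationError(QoracError):
    """The optimality-system Jacobian is (numerically) singular, so the
    predicted optimum is not a well-defined function of the sensors.

    ``condition_number`` holds the estimated condition number at failure.
    """

    def __init__(self, condition_number: float, message: str | None = None):
        self.condition_number = condition_number
        super().__init__(message or "implicit-function-theorem violation: "
                         f"optimality Jacobian condition number "
                         f"{condition_number:.3e}")


class ControllerSolverError(QoracError):
    """Newton iteration for the predicted optimum failed to converge
    (distinct from an IFT violation: the Jacobian was usable but the
    iteration did not reach tolerance)."""


class DegenerateStateError(QoracError):
    """The synthesis-rate normalising sum vanished exactly."""


class SimulationError(QoracError):
    """ODE integration failed; carries segment index and time."""

    def __init__(self, message: str, segment: int | None = None,
                 time: float | None = None):
        self.segment = segment
        self.time = time
        super().__init__(message)
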
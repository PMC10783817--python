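"""Exception hierarchy."""

__all__ = [
    "ECFluxError",
    "InfeasibleError",
    "UnboundedError",
    "RelaxationError",
    "GrowthUnreachableError",
    "FixtureError",
]


class ECFluxError(Exception):
    """Base class for all package errors."""


class InfeasibleError(ECFluxError):
    """The optimization problem has no feasible solution."""


class UnboundedError(ECFluxError):
    """The optimization problem is unbounded in the objective direction."""


class RelaxationError(ECFluxError):
    """Infeasibility persists even after relaxing the targeted enzyme set.

    Raised when elastic/MILP relaxation of every targeted enzyme row cannot
    restore feasibility, i.e. the conflict involves non-enzyme constraints
    (growth or uptake bounds, stoichiometry)."""


class GrowthUnreachableError(ECFluxError):
    """Greedy removal exhausted the bounded enzymes without reaching the target."""


class FixtureError(ECFluxError):
    """A synthetic fixture could not be constructed as requested."""
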
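"""Enzyme-aware flux analysis: FBA, FVA and average enzyme saturation.

FBA solves ``max c'v  s.t.  Sv = 0,  lb <= v <= ub`` with the enzyme rows of
the EC model included.  FVA fixes the objective at (a fraction of) its
optimum and scans each reaction's attainable flux range; the comparison
protocol optionally pins the limiting uptake exchange to its minimal value
inside the optimum first, and can block the opposite half of legacy split
reaction pairs to remove spurious variability.  The saturation statistic is
the mean of ``supply_p / ub_p`` over enzymes with non-zero supply bound.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Optional

import pandas as pd
from cobra.exceptions import OptimizationError
from cobra.util.solver import fix_objective_as_constraint

from .ec_model import DEFAULT_SUPPLY_UB, ECModel
from .exceptions import InfeasibleError, UnboundedError

__all__ = [
    "Solution",
    "SaturationReport",
    "fba",
    "fva",
    "average_saturation",
]

#: Primal values above this count an enzyme as active (LP noise floor).
ACTIVE_THRESHOLD = 1e-7

_REV_PATTERN = re.compile(r"^(?P<base>.+)_REV(?:No\d+)?$")


@dataclass
class Solution:
    """An optimal FBA solution.

    ``protein_reduced_costs`` holds, per enzyme, the marginal objective gain
    of one extra unit of enzyme supply (the shadow price of the supply bound);
    it is only populated for pure LPs (no integer variables).
    """

    objective_value: float
    fluxes: pd.Series
    protein_supplies: pd.Series
    protein_reduced_costs: Optional[pd.Series]
    status: str


@dataclass
class SaturationReport:
    """Average enzyme saturation, overall and restricted to active enzymes."""

    overall: float
    active_only: float
    n_bounded: int
    n_active: int


def _check_status(status: str) -> None:
    if status == "infeasible":
        raise InfeasibleError("FBA problem is infeasible under the current bounds")
    if status in ("unbounded", "infeasible_or_unbounded"):
        raise UnboundedError("FBA problem is unbounded")
    if status != "optimal":
        raise InfeasibleError(f"solver returned non-optimal status {status!r}")


def fba(ec: ECModel) -> Solution:
    """Solve the (enzyme-constrained) flux balance problem.

    Raises
    ------
    InfeasibleError, UnboundedError
        Signaled distinctly; never returned silently.
    """
    model = ec.model
    try:
        sol = model.optimize()
    except OptimizationError:
        _check_status(model.solver.status)
        raise  # pragma: no cover - _check_status always raises here
    _check_status(sol.status)
    supplies = pd.Series(
        {pid: sol.fluxes[pid + "_supply"] for pid in ec.proteins}, dtype=float
    )
    reduced = None
    if sol.reduced_costs is not None and not _has_integers(ec):
        reduced = pd.Series(
            {pid: sol.reduced_costs[pid + "_supply"] for pid in ec.proteins},
            dtype=float,
        )
    return Solution(
        objective_value=sol.objective_value,
        fluxes=sol.fluxes,
        protein_supplies=supplies,
        protein_reduced_costs=reduced,
        status=sol.status,
    )


def _has_integers(ec: ECModel) -> bool:
    return any(v.type in ("binary", "integer") for v in ec.model.solver.variables)


def split_counterpart(ec: ECModel, reaction_id: str) -> Optional[str]:
    """The opposite half of a legacy split reversible pair, if present."""
    m = _REV_PATTERN.match(reaction_id)
    candidate = m.group("base") if m else reaction_id + "_REV"
    if candidate in ec.model.reactions and candidate != reaction_id:
        return candidate
    return None


def fva(
    ec: ECModel,
    reactions: Optional[Iterable[str]] = None,
    *,
    objective_fraction: float = 1.0,
    fix_uptake: Optional[str] = None,
    block_opposite_split: bool = False,
) -> pd.DataFrame:
    """Flux variability analysis at a fixed objective fraction.

    Parameters
    ----------
    reactions
        Reaction ids to scan (default: all, including enzyme supplies).
    objective_fraction
        The objective is constrained to at least this fraction of its FBA
        optimum (default 1.0, i.e. fixed at the optimum).
    fix_uptake
        Id of an uptake exchange to pin first: inside the optimal objective
        space its consumption is minimized and the exchange fixed there, so
        variability is compared at equal substrate usage.
    block_opposite_split
        While scanning a reaction with a legacy ``_REV`` counterpart, bound
        the counterpart to zero (removes spurious two-way variability of
        split reversible pairs).

    Returns
    -------
    DataFrame indexed by reaction id with columns ``minimum``/``maximum``.
    """
    work = ec.copy()
    model = work.model
    opt = model.slim_optimize()
    if opt != opt:  # NaN -> infeasible
        raise InfeasibleError("model is infeasible; cannot run FVA")
    fix_objective_as_constraint(model, fraction=objective_fraction)
    if fix_uptake is not None:
        ex = model.reactions.get_by_id(fix_uptake)
        # uptake is a negative exchange flux: minimal consumption = max flux
        model.objective = ex
        model.objective_direction = "max"
        v = model.slim_optimize()
        if v != v:
            raise InfeasibleError("infeasible while minimizing the uptake")
        ex.bounds = (v, v)
    ids = [r.id for r in model.reactions] if reactions is None else list(reactions)
    records = {}
    for rid in ids:
        rxn = model.reactions.get_by_id(rid)
        saved = None
        if block_opposite_split:
            other = split_counterpart(work, rid)
            if other is not None:
                counterpart = model.reactions.get_by_id(other)
                saved = counterpart.bounds
                counterpart.bounds = (0.0, 0.0)
        model.objective = rxn
        lo_hi = []
        for direction in ("min", "max"):
            model.objective_direction = direction
            val = model.slim_optimize()
            if val != val:
                raise InfeasibleError(f"FVA subproblem infeasible for {rid}")
            lo_hi.append(val)
        if saved is not None:
            counterpart.bounds = saved
        records[rid] = (min(lo_hi), max(lo_hi))
    return pd.DataFrame.from_dict(
        records, orient="index", columns=["minimum", "maximum"]
    )


def average_saturation(
    ec: ECModel,
    solution: Optional[Solution] = None,
    *,
    active_threshold: float = ACTIVE_THRESHOLD,
) -> SaturationReport:
    """Mean enzyme saturation ``supply_p / ub_p`` at an optimal solution.

    ``overall`` averages over every enzyme with an explicit non-zero supply
    bound (enzymes left at the default unbounded supply are not meaningfully
    saturable and are excluded); ``active_only`` restricts further to
    enzymes with supply above ``active_threshold``.
    """
    if solution is None:
        solution = fba(ec)
    ratios = {}
    for pid in ec.proteins:
        ub = ec.protein_bound(pid)
        if 0 < ub < DEFAULT_SUPPLY_UB:
            ratios[pid] = solution.protein_supplies[pid] / ub
    if not ratios:
        raise ValueError("no enzyme with a non-zero supply bound")
    active = {
        pid: r
        for pid, r in ratios.items()
        if solution.protein_supplies[pid] > active_threshold
    }
    overall = sum(ratios.values()) / len(ratios)
    active_only = sum(active.values()) / len(active) if active else 0.0
    return SaturationReport(
        overall=overall,
        active_only=active_only,
        n_bounded=len(ratios),
        n_active=len(active),
    )
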
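"""Relaxation of infeasible enzyme-constrained models.

When measured enzyme concentrations (plus a fixed growth rate and uptake
bounds) make a model infeasible, these algorithms compute an irreducibly
inconsistent set (IIS) of enzyme constraints and how much each must be
relaxed:

* ``elastic_filter`` — elastic filtering LP: one elastic variable
  ``e in [0, 1000]`` per targeted enzyme row acts as extra supply; minimize
  ``sum e`` (optionally together with ``-Z``, the original objective).  The
  LP is iterated, dropping elastics found active (primal > 1e-7) from the
  objective, which expands the IIS until no further elastics activate.
* ``milp_iis`` — minimal-cardinality MILP: per enzyme row a binary ``i``
  and a compensating continuous ``l in [0, K]`` enter as ``-K*i + l``
  (extra supply ``K*i - l >= 0``); minimizing ``sum i`` counts the relaxed
  enzymes.  ``K = 1000`` blocks any enzyme supply when active.  The
  formulation exploits that enzyme rows only ever need upper-direction
  relaxation, avoiding quadratic terms.  The optimal set need not be
  unique; validate feasibility/minimality rather than identity.
* ``greedy_relaxation`` — iterative removal guided by the shadow price of
  the supply bound (most growth-limiting enzyme first) until a target
  growth is reached.

All methods leave the input model untouched and raise
:class:`~ecflux.exceptions.RelaxationError` when the infeasibility is not
attributable to the targeted enzyme set (e.g. inconsistent growth/uptake
bounds).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

from .ec_model import DEFAULT_SUPPLY_UB, ECModel
from .exceptions import GrowthUnreachableError, RelaxationError
from .flux_analysis import fba

__all__ = [
    "RELAXATION_THRESHOLD",
    "ELASTIC_BOUND",
    "BIG_K",
    "RelaxationResult",
    "elastic_filter",
    "milp_iis",
    "greedy_relaxation",
    "apply_relaxation",
]

#: Elastic/binary primals above this are reported as part of the IIS
#: (the numerical noise floor of the LP solvers).
RELAXATION_THRESHOLD = 1e-7

#: Upper bound of each elastic variable, mmol/gDW/h.
ELASTIC_BOUND = 1000.0

#: Big constant multiplying the MILP binaries; large enough to block any
#: enzyme supply (the conventional COBRA flux bound).
BIG_K = 1000.0

#: Cushion added when re-applying LP relaxation values as bounds, so the
#: relaxed model is strictly feasible despite floating-point round-off.
_APPLY_EPS = 1e-9


@dataclass
class RelaxationResult:
    """Outcome of one relaxation run.

    ``relaxation_values`` holds, per IIS member, the extra supply
    (mmol/gDW/h) needed beyond the measured bound: the elastic primal for
    the LP methods, ``K*i - l`` for the MILP, and the removed headroom
    (default bound minus measured bound) for the greedy method.
    ``first_iteration_total`` is the minimal total violation found by the
    first LP solve (before IIS expansion), the quantity an all-slack LP
    oracle must reproduce.
    """

    iis: set[str] = field(default_factory=set)
    relaxation_values: dict[str, float] = field(default_factory=dict)
    method: str = "lp"
    iterations: int = 0
    objective_value: float = 0.0
    feasible_after: bool = True
    first_iteration_total: Optional[float] = None


def _is_feasible(ec: ECModel) -> bool:
    ec.model.solver.optimize()
    return ec.model.solver.status == "optimal"


def _empty_result(method: str) -> RelaxationResult:
    return RelaxationResult(method=method, iterations=0, feasible_after=True)


def _target_ids(ec: ECModel, target_proteins) -> list[str]:
    if target_proteins is None:
        return sorted(ec.proteins)
    unknown = set(target_proteins) - set(ec.proteins)
    if unknown:
        raise ValueError(f"unknown protein ids: {sorted(unknown)}")
    return sorted(target_proteins)


def elastic_filter(
    ec: ECModel,
    target_proteins=None,
    include_objective: bool = False,
    *,
    threshold: float = RELAXATION_THRESHOLD,
) -> RelaxationResult:
    """Elastic filtering LP over the targeted enzyme rows.

    If the model is already feasible an empty result is returned.  The LP
    minimizes the total elastic relaxation (optionally ``-Z + sum e`` so
    the original objective is pursued simultaneously); elastics found
    active are moved out of the objective and the LP re-solved until no new
    elastic activates, accumulating the IIS.
    """
    method = "lp_objective" if include_objective else "lp"
    if _is_feasible(ec):
        return _empty_result(method)
    work = ec.copy()
    targets = _target_ids(work, target_proteins)
    solver = work.model.solver
    elastics = {}
    for pid in targets:
        e = work.model.problem.Variable(f"{pid}_elastic", lb=0.0, ub=ELASTIC_BOUND)
        work.model.add_cons_vars([e])
        elastics[pid] = e
    solver.update()
    for pid in targets:
        # extra supply enters the balance row like the supply column: -e
        work.balance_constraint(pid).set_linear_coefficients({elastics[pid]: -1.0})

    base_objective = work.model.solver.objective.expression
    iis: set[str] = set()
    iterations = 0
    first_total = None
    while True:
        expr = sum(elastics[pid] for pid in targets if pid not in iis)
        if include_objective:
            expr = expr - base_objective
        work.model.objective = work.model.problem.Objective(expr, direction="min")
        solver.optimize()
        if solver.status != "optimal":
            raise RelaxationError(
                "infeasible even with elastic relaxation of all targeted "
                "enzymes; the conflict involves non-enzyme constraints"
            )
        iterations += 1
        if first_total is None:
            first_total = sum(elastics[pid].primal for pid in targets)
        found = {
            pid
            for pid in targets
            if pid not in iis and elastics[pid].primal > threshold
        }
        if not found:
            break
        iis |= found
    # IIS membership follows the reporting threshold; the applied values
    # keep every positive primal so that apply_relaxation restores
    # feasibility exactly (sub-threshold slack is real, just not reported
    # as an IIS member)
    values = {
        pid: float(elastics[pid].primal)
        for pid in targets
        if elastics[pid].primal > 1e-12
    }
    return RelaxationResult(
        iis={pid for pid in iis if pid in values and values[pid] > threshold},
        relaxation_values=values,
        method=method,
        iterations=iterations,
        objective_value=float(work.model.solver.objective.value),
        feasible_after=True,
        first_iteration_total=float(first_total),
    )


def milp_iis(
    ec: ECModel,
    target_proteins=None,
    *,
    expand: bool = False,
    big_k: float = BIG_K,
) -> RelaxationResult:
    """Minimal-cardinality IIS via the big-K MILP.

    With ``expand=True`` the MILP is iterated like the elastic filter:
    binaries found active are dropped from the objective and the problem
    re-solved, accumulating a (possibly larger) IIS.
    """
    method = "milp"
    if _is_feasible(ec):
        return _empty_result(method)
    work = ec.copy()
    targets = _target_ids(work, target_proteins)
    solver = work.model.solver
    binaries, comps = {}, {}
    for pid in targets:
        binaries[pid] = work.model.problem.Variable(f"{pid}_iis", type="binary")
        comps[pid] = work.model.problem.Variable(f"{pid}_comp", lb=0.0, ub=big_k)
    work.model.add_cons_vars(list(binaries.values()) + list(comps.values()))
    solver.update()
    for pid in targets:
        # extra supply K*i - l enters the balance row as -(K*i - l)
        work.balance_constraint(pid).set_linear_coefficients(
            {binaries[pid]: -big_k, comps[pid]: 1.0}
        )

    iis: set[str] = set()
    iterations = 0
    while True:
        expr = sum(binaries[pid] for pid in targets if pid not in iis)
        work.model.objective = work.model.problem.Objective(expr, direction="min")
        solver.optimize()
        if solver.status != "optimal":
            raise RelaxationError(
                "infeasible even with all targeted enzyme rows relaxed; the "
                "conflict involves non-enzyme constraints"
            )
        iterations += 1
        found = {
            pid for pid in targets if pid not in iis and binaries[pid].primal > 0.5
        }
        if not found or not expand:
            iis |= found
            break
        iis |= found
    values = {
        pid: max(big_k * binaries[pid].primal - comps[pid].primal, 0.0) for pid in iis
    }
    return RelaxationResult(
        iis=iis,
        relaxation_values=values,
        method=method,
        iterations=iterations,
        objective_value=float(work.model.solver.objective.value),
        feasible_after=True,
    )


def greedy_relaxation(
    ec: ECModel,
    target_growth: float,
    *,
    tolerance: float = 1e-9,
) -> RelaxationResult:
    """Remove enzyme bounds one by one, guided by their shadow prices.

    Each round solves FBA (the objective reaction's lower bound is released
    so the problem is optimizable even if growth was pinned); if the
    optimum is below ``target_growth``, the bounded enzyme whose supply
    bound has the largest shadow-price magnitude — ties broken by
    lexicographic id — is unbounded.  Capped at one removal per enzyme;
    raises :class:`GrowthUnreachableError` if the target stays out of reach
    with every enzyme unbounded (a non-enzyme bottleneck).
    """
    if not target_growth > 0:
        raise ValueError("target_growth must be > 0")
    work = ec.copy()
    from cobra.util.solver import linear_reaction_coefficients

    for rxn in linear_reaction_coefficients(work.model):
        rxn.lower_bound = min(rxn.lower_bound, 0.0)

    removed: list[str] = []
    final_obj = float("nan")
    for _ in range(len(work.proteins) + 1):
        try:
            sol = fba(work)
        except Exception as exc:
            raise RelaxationError(
                "FBA infeasible under the model's fixed bounds; greedy "
                "removal needs an optimizable problem — relax fixed "
                "constraints or use elastic_filter/milp_iis"
            ) from exc
        final_obj = sol.objective_value
        if final_obj >= target_growth - tolerance:
            break
        candidates = [
            pid
            for pid in sorted(work.proteins)
            if pid not in removed and work.protein_bound(pid) < DEFAULT_SUPPLY_UB
        ]
        if not candidates:
            raise GrowthUnreachableError(
                f"growth {target_growth} unreachable: optimum {final_obj} with "
                "all enzyme bounds removed (non-enzyme bottleneck)"
            )
        if sol.protein_reduced_costs is None:
            raise RelaxationError("shadow prices unavailable (integer variables?)")
        best = max(
            candidates,
            key=lambda pid: (abs(sol.protein_reduced_costs[pid]), _reverse_id(pid)),
        )
        work.set_protein_bound(best, DEFAULT_SUPPLY_UB)
        removed.append(best)
    else:
        raise GrowthUnreachableError(
            f"growth {target_growth} unreachable after removing all enzyme bounds"
        )
    values = {
        pid: DEFAULT_SUPPLY_UB - ec.protein_bound(pid) for pid in removed
    }
    return RelaxationResult(
        iis=set(removed),
        relaxation_values=values,
        method="greedy",
        iterations=len(removed),
        objective_value=final_obj,
        feasible_after=True,
    )


class _reverse_id(str):
    """Order helper: ties on shadow price pick the lexicographically
    smallest id under ``max``."""

    def __lt__(self, other):  # max() picks the *largest*; invert
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def apply_relaxation(ec: ECModel, result: RelaxationResult) -> ECModel:
    """Return a copy of ``ec`` with the relaxation applied.

    LP methods raise each IIS member's supply bound by its relaxation
    value; MILP and greedy results unbound the IIS members entirely.  The
    returned model is feasible.
    """
    unknown = result.iis - set(ec.proteins)
    if unknown:
        raise ValueError(
            f"relaxation refers to proteins absent from the model: {sorted(unknown)}"
        )
    out = ec.copy()
    if result.method in ("lp", "lp_objective"):
        for pid, value in result.relaxation_values.items():
            out.set_protein_bound(
                pid, out.protein_bound(pid) + value + _APPLY_EPS
            )
    else:
        for pid in result.iis:
            out.set_protein_bound(pid, DEFAULT_SUPPLY_UB)
    return out
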
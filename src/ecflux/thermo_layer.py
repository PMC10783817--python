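"""Minimal thermodynamic constraint layer and layered FVA comparison.

Second-law direction coupling: a reaction with a known standard transformed
Gibbs energy may only carry forward flux if its transformed Gibbs energy

    dG' = dG'0 + R*T * sum_i s_i * ln(c_i)

can be negative within the metabolite concentration ranges (and mirrored
for the backward direction).  Concentrations enter as log-transformed
variables so the coupling stays linear; a binary direction variable ``z``
and a big-M constant tie flux sign to the sign of ``dG'``:

    v_fwd <= M * z_f           dG' <= -delta + M * (1 - z_f)
    v_rev <= M * z_b          -dG' <= -delta + M * (1 - z_b)
    z_f + z_b <= 1

Reactions without a Gibbs energy receive no constraint; reactions already
unidirectional keep their direction.  ``layered_fva`` runs the flux
variability comparison across combinations of constraint layers
(thermodynamics, proteomics, pool), relaxing infeasible combinations with
the minimal-cardinality MILP followed by a greedy keep-back filter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd

from .ec_model import ECModel
from .flux_analysis import fva
from .relaxation import milp_iis

__all__ = [
    "ThermoData",
    "add_thermo_constraints",
    "layered_fva",
    "LayeredResult",
    "DEFAULT_LOG_CONC",
]

#: Default metabolite log-concentration range, ln of molar:
#: 1e-6 M to 0.02 M, the span conventionally assumed for cytosolic
#: metabolites when no measurement is available.
DEFAULT_LOG_CONC = (math.log(1e-6), math.log(2e-2))

#: Minimum driving force (kJ/mol) breaking the dG' = 0 degeneracy.
MIN_DRIVING_FORCE = 1e-3

#: Big-M for the direction coupling, consistent with the flux-bound
#: convention.
BIG_M = 1000.0


@dataclass
class ThermoData:
    """Thermodynamic inputs: per-reaction dG'0 and concentration ranges.

    ``dg0`` maps reaction id -> standard transformed Gibbs energy (kJ/mol);
    reactions absent from the map are unconstrained.  ``log_conc`` maps
    metabolite id -> (ln c_min, ln c_max) with :data:`DEFAULT_LOG_CONC` as
    fallback.  ``gas_constant`` is in kJ/mol/K.
    """

    dg0: Mapping[str, float] = field(default_factory=dict)
    log_conc: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    temperature: Optional[float] = 298.15
    gas_constant: float = 8.314e-3


def add_thermo_constraints(
    ec: ECModel,
    data: ThermoData,
    *,
    big_m: float = BIG_M,
    min_driving_force: float = MIN_DRIVING_FORCE,
) -> ECModel:
    """Add second-law direction coupling in place; returns the model.

    Raises ``ValueError`` if the temperature is missing or ``big_m`` is
    smaller than an existing flux bound (it must be non-binding for any
    allowed flux).
    """
    if data.temperature is None:
        raise ValueError("thermodynamic constraints need a temperature")
    rt = data.gas_constant * data.temperature
    model = ec.model
    constrained = [rid for rid in sorted(data.dg0) if rid in model.reactions]
    max_bound = max(
        (
            max(abs(model.reactions.get_by_id(rid).lower_bound),
                abs(model.reactions.get_by_id(rid).upper_bound))
            for rid in constrained
        ),
        default=0.0,
    )
    if big_m < max_bound:
        raise ValueError(
            f"big_m={big_m} is smaller than the largest flux bound "
            f"{max_bound}; the coupling would clip feasible fluxes"
        )

    lnc_vars: dict[str, object] = {}

    def lnc(met_id: str):
        if met_id not in lnc_vars:
            lo, hi = data.log_conc.get(met_id, DEFAULT_LOG_CONC)
            v = model.problem.Variable(f"lnc_{met_id}", lb=lo, ub=hi)
            model.add_cons_vars([v])
            lnc_vars[met_id] = v
        return lnc_vars[met_id]

    new_cons = []
    for rid in constrained:
        rxn = model.reactions.get_by_id(rid)
        dg0 = data.dg0[rid]
        # linear part of dG' (the dG'0 constant moves onto the bound)
        dg_lin = rt * sum(
            coef * lnc(met.id) for met, coef in rxn.metabolites.items()
        )
        z_f = model.problem.Variable(f"{rid}_thermo_fwd", type="binary")
        z_b = model.problem.Variable(f"{rid}_thermo_rev", type="binary")
        model.add_cons_vars([z_f, z_b])
        new_cons.extend(
            [
                model.problem.Constraint(
                    rxn.forward_variable - big_m * z_f,
                    ub=0, name=f"{rid}_flux_fwd_coupling",
                ),
                model.problem.Constraint(
                    rxn.reverse_variable - big_m * z_b,
                    ub=0, name=f"{rid}_flux_rev_coupling",
                ),
                model.problem.Constraint(
                    dg_lin + big_m * z_f,
                    ub=big_m - min_driving_force - dg0,
                    name=f"{rid}_dg_fwd",
                ),
                model.problem.Constraint(
                    -dg_lin + big_m * z_b,
                    ub=big_m - min_driving_force + dg0,
                    name=f"{rid}_dg_rev",
                ),
                model.problem.Constraint(
                    z_f + z_b, ub=1, name=f"{rid}_direction_choice"
                ),
            ]
        )
    model.add_cons_vars(new_cons)
    model.solver.update()
    return ec


@dataclass
class LayeredResult:
    """FVA results per layer combination, plus relaxation bookkeeping."""

    fva: dict[frozenset, pd.DataFrame]
    removed_proteins: dict[frozenset, set[str]]


def _greedy_keepback(ec: ECModel, iis: set[str], bounds: Mapping[str, float]) -> set[str]:
    """Try to re-tighten IIS members one by one, keeping those that stay
    feasible; returns the minimal removed set found."""
    removed = set(iis)
    for pid in sorted(iis):
        ec.set_protein_bound(pid, bounds[pid])
        ec.model.solver.optimize()
        if ec.model.solver.status == "optimal":
            removed.discard(pid)
        else:
            from .ec_model import DEFAULT_SUPPLY_UB

            ec.set_protein_bound(pid, DEFAULT_SUPPLY_UB)
    return removed


def layered_fva(
    ec: ECModel,
    combinations: Sequence[Iterable[str]],
    *,
    thermo_data: Optional[ThermoData] = None,
    measurements: Optional[Mapping[str, float]] = None,
    pool_total: Optional[float] = None,
    pool_proteins: Optional[Iterable[str]] = None,
    fva_kwargs: Optional[dict] = None,
) -> LayeredResult:
    """FVA under each requested combination of constraint layers.

    Layer names: ``"thermo"`` (needs ``thermo_data``), ``"proteomics"``
    (needs ``measurements``), ``"pool"`` (needs ``pool_total``).  The empty
    combination — the plain baseline with enzyme bounds released — is
    always computed.

    All combinations are compared at one common growth: the optimum of the
    thermodynamics-constrained model when a thermo layer is requested,
    otherwise the smallest optimum across the requested combinations, so
    that the per-reaction flux intervals of nested constraint sets are
    themselves nested.  A combination that cannot reach the common growth
    because of its enzyme bounds is first relaxed with the
    minimal-cardinality MILP followed by a greedy keep-back filter over the
    IIS; the finally removed enzymes are reported per combination.
    """
    from .ec_model import DEFAULT_SUPPLY_UB
    from cobra.util.solver import linear_reaction_coefficients

    fva_kwargs = dict(fva_kwargs or {})
    combos = [frozenset(c) for c in combinations]
    if frozenset() not in combos:
        combos.insert(0, frozenset())
    known = {"thermo", "proteomics", "pool"}
    for combo in combos:
        if not combo <= known:
            raise ValueError(f"unknown layers: {sorted(combo - known)}")

    def build(combo: frozenset) -> tuple[ECModel, dict[str, float]]:
        work = ec.copy()
        work.release_protein_bounds()
        applied_bounds: dict[str, float] = {}
        if "pool" in combo:
            if pool_total is None:
                raise ValueError("pool layer requested without pool_total")
            work.constrain_pool(pool_total, pool_proteins)
        if "proteomics" in combo:
            if measurements is None:
                raise ValueError("proteomics layer requested without measurements")
            work.limit_proteins(measurements)
            applied_bounds = {
                pid: v for pid, v in measurements.items() if pid in work.proteins
            }
        if "thermo" in combo:
            if thermo_data is None:
                raise ValueError("thermo layer requested without thermo_data")
            add_thermo_constraints(work, thermo_data)
        return work, applied_bounds

    # common growth: the thermodynamic solution when thermo is in play,
    # else the tightest optimum across the requested combinations
    if any("thermo" in c for c in combos) and thermo_data is not None:
        ref, _ = build(frozenset({"thermo"}))
        growth = ref.model.slim_optimize()
    else:
        growth = min(build(c)[0].model.slim_optimize() for c in combos)
    if growth != growth:
        raise ValueError("reference combination is infeasible")

    results: dict[frozenset, pd.DataFrame] = {}
    removed: dict[frozenset, set[str]] = {}
    for combo in combos:
        work, applied_bounds = build(combo)
        obj_rxns = list(linear_reaction_coefficients(work.model))
        if len(obj_rxns) != 1:
            raise ValueError("layered FVA needs a single-reaction objective")
        work.model.reactions.get_by_id(obj_rxns[0].id).bounds = (growth, growth)
        work.model.solver.optimize()
        combo_removed: set[str] = set()
        if work.model.solver.status != "optimal" and applied_bounds:
            iis_result = milp_iis(work)
            for pid in iis_result.iis:
                work.set_protein_bound(pid, DEFAULT_SUPPLY_UB)
            combo_removed = _greedy_keepback(work, iis_result.iis, applied_bounds)
        results[combo] = fva(work, **fva_kwargs)
        removed[combo] = combo_removed
    return LayeredResult(fva=results, removed_proteins=removed)
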
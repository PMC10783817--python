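"""Programmatic generation of small enzyme-constrained models.

Every generator is deterministic for a given seed so that property tests and
benchmarks are reproducible without any downloaded data.

The toy network is the classic four-metabolite two-reaction chain

    R1: A + 2 B -> C        (catalyzed by P1)
    R2: A + C   -> 4 D      (catalyzed by P2)

with supply exchanges for A (ub 10) and B (ub 20), a free export of D, and
D export as the objective.  Its plain-FBA optimum is 20 (the C balance
forces v1 = v2 = 5 given the A supply of 10).  Optional extra branches add
independent substrate->D routes, each with its own enzyme, so that several
enzymes are simultaneously active and uniquely determined at the optimum —
the setting needed for ground-truth recovery tests of the relaxation
algorithms.
"""

from __future__ import annotations

from typing import Optional

import cobra
import numpy as np
from cobra.util.solver import linear_reaction_coefficients

from .ec_model import DEFAULT_SUPPLY_UB, ECModel, Protein
from .exceptions import FixtureError
from .flux_analysis import ACTIVE_THRESHOLD, fba

__all__ = ["make_toy_ec_model", "make_infeasible_case", "make_core_ec_model"]


def make_toy_ec_model(
    n_extra_branches: int = 0,
    seed: int = 0,
    *,
    p1_concentration: Optional[float] = None,
    p2_concentration: Optional[float] = None,
    p1_kcat: float = 10.0,
    p2_kcat: float = 20.0,
) -> ECModel:
    """Build the toy EC model, optionally widened with seeded branches.

    Each extra branch ``i`` is an independent route ``S_i -> D`` fed by its
    own exchange (seeded ub in [2, 8]) and catalyzed by enzyme ``PB_i`` with
    a seeded kcat in [5, 50] 1/h and mw in [5, 50] g/mmol.
    """
    rng = np.random.default_rng(seed)
    m = cobra.Model("toy_ec")
    mets = {x: cobra.Metabolite(x, compartment="c") for x in "ABCD"}

    def rxn(rid, stoich, lb, ub):
        r = cobra.Reaction(rid)
        r.bounds = (lb, ub)
        m.add_reactions([r])
        r.add_metabolites(stoich)
        return r

    rxn("R1", {mets["A"]: -1, mets["B"]: -2, mets["C"]: 1}, 0, DEFAULT_SUPPLY_UB)
    rxn("R2", {mets["A"]: -1, mets["C"]: -1, mets["D"]: 4}, 0, DEFAULT_SUPPLY_UB)
    rxn("EX_A", {mets["A"]: 1}, 0, 10)
    rxn("EX_B", {mets["B"]: 1}, 0, 20)
    rxn("EX_D", {mets["D"]: -1}, 0, DEFAULT_SUPPLY_UB)

    for i in range(n_extra_branches):
        s = cobra.Metabolite(f"S{i}", compartment="c")
        ub = float(np.round(rng.uniform(2, 8), 3))
        rxn(f"EX_S{i}", {s: 1}, 0, ub)
        rxn(f"RB{i}", {s: -1, mets["D"]: 1}, 0, DEFAULT_SUPPLY_UB)

    m.objective = "EX_D"

    ec = ECModel(m)
    ec.add_protein("R1", Protein("P1", concentration=p1_concentration, mw=10.0), p1_kcat)
    ec.add_protein("R2", Protein("P2", concentration=p2_concentration, mw=25.0), p2_kcat)
    for i in range(n_extra_branches):
        kcat = float(np.round(rng.uniform(5, 50), 3))
        mw = float(np.round(rng.uniform(5, 50), 3))
        ec.add_protein(f"RB{i}", Protein(f"PB{i}", mw=mw), kcat)
    return ec


def make_infeasible_case(
    model: ECModel,
    n_violations: int = 1,
    magnitude: float = 0.5,
    seed: int = 0,
) -> tuple[ECModel, set[str]]:
    """Tighten enzyme bounds below their required usage at the optimum.

    The input model is solved, ``n_violations`` enzymes active at the
    optimum are drawn (seeded, without replacement), their supply bounds are
    cut to ``required * (1 - magnitude)``, and the objective reaction is
    fixed at the pre-tightening optimum.  The returned model is verified
    infeasible; the second element is the ground-truth violated enzyme set.

    ``magnitude`` is the relative reduction, in (0, 1]; zero would leave the
    model feasible and is rejected.
    """
    if not 0 < magnitude <= 1:
        raise FixtureError(f"magnitude must be in (0, 1], got {magnitude}")
    rng = np.random.default_rng(seed)
    sol = fba(model)
    active = sorted(
        pid for pid in model.proteins if sol.protein_supplies[pid] > ACTIVE_THRESHOLD
    )
    if len(active) < n_violations:
        raise FixtureError(
            f"requested {n_violations} violations but only {len(active)} "
            "enzymes are active at the optimum"
        )
    chosen = sorted(rng.choice(active, size=n_violations, replace=False).tolist())
    out = model.copy()
    for pid in chosen:
        required = float(sol.protein_supplies[pid])
        tightened = float(f"{required * (1.0 - magnitude):.9g}")
        out.proteins[pid].concentration = tightened
        out.set_protein_bound(pid, tightened)
    obj_rxns = list(linear_reaction_coefficients(out.model))
    if len(obj_rxns) != 1:
        raise FixtureError("model must have a single-reaction objective")
    target = float(f"{sol.objective_value:.9g}")
    obj_rxns[0].bounds = (target, target)
    out.model.solver.optimize()
    if out.model.solver.status == "optimal":
        raise FixtureError(
            "tightening did not render the model infeasible; the chosen "
            "enzymes were not binding at the fixed optimum"
        )
    return out, set(chosen)


def make_core_ec_model(n_proteins: int = 55, seed: int = 0) -> ECModel:
    """A synthetic enzyme-constrained E. coli core model.

    Decorates the bundled E. coli core network (95 reactions, 72
    metabolites) with ``n_proteins`` synthetic enzymes: catalyzed reactions
    are drawn (seeded) from the gene-associated internal reactions, kcats
    are log-uniform in [1e3, 1e6] 1/h (centered near the ~10/s median of
    measured turnover numbers) and molecular weights uniform in [20, 100]
    g/mmol.  Enzyme ids are synthetic accessions ``P90000``-style; the
    object is a stand-in for curated enzyme-constrained core models, not a
    reconstruction.
    """
    rng = np.random.default_rng(seed)
    core = cobra.io.load_model("textbook")
    candidates = sorted(
        r.id
        for r in core.reactions
        if r.genes and not r.boundary and "biomass" not in r.id.lower()
    )
    if n_proteins > len(candidates):
        raise FixtureError(
            f"core model has only {len(candidates)} catalyzable reactions"
        )
    chosen = sorted(rng.choice(candidates, size=n_proteins, replace=False).tolist())
    ec = ECModel(core)
    for i, rid in enumerate(chosen):
        kcat = float(f"{10 ** rng.uniform(3, 6):.6g}")
        mw = float(np.round(rng.uniform(20, 100), 2))
        ec.add_protein(rid, Protein(f"P9{i:04d}", mw=mw), kcat)
    return ec
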
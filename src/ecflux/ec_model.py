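"""Enzyme-constrained metabolic models (GECKO formulation).

An enzyme-constrained (EC) model extends a stoichiometric model with one
pseudometabolite row per enzyme and one supply pseudoexchange column per
enzyme.  An enzyme ``p`` catalyzing reaction ``j`` with turnover number
``kcat`` (1/h) enters ``j`` with stoichiometric coefficient ``-1/kcat``, so
at steady state the supplied amount of ``p`` (mmol/gDW) balances its total
usage ``sum_j v_j / kcat_{p,j}``.  The supply upper bound carries the
measured enzyme concentration; alternatively a pool constraint
``sum_p mw_p * supply_p <= total`` caps the aggregate enzyme mass.

Reversible catalyzed reactions are handled internally: enzyme usage charges
``|v_j| / kcat`` by summing the solver's forward and reverse flux variables,
so reactions are never split in the persisted model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

import cobra

__all__ = [
    "DEFAULT_SUPPLY_UB",
    "Protein",
    "PoolConstraint",
    "MatchReport",
    "ECModel",
    "add_protein",
    "constrain_pool",
    "limit_proteins",
]

#: Default (effectively unbounded) enzyme supply, mmol/gDW/h.  Matches the
#: conventional COBRA default flux bound of 1000.
DEFAULT_SUPPLY_UB = 1000.0

#: Seconds per hour; used when turnover numbers are supplied in 1/s.
_S_PER_H = 3600.0

_SUPPLY_SUFFIX = "_supply"
_BALANCE_SUFFIX = "_balance"
_POOL_CONSTRAINT_ID = "protein_pool"


@dataclass
class Protein:
    """One enzyme of an EC model.

    Parameters
    ----------
    id
        UniProt-style accession used as the SBML species id.
    concentration
        Measured abundance in mmol/gDW; maps onto the supply upper bound.
        ``None`` means unmeasured (supply bounded only by the default or by
        the pool).
    mw
        Molecular weight in g/mmol (numerically kDa); required for pool
        membership.
    kcats
        Turnover numbers per catalyzed reaction id, in 1/h.
    """

    id: str
    concentration: Optional[float] = None
    mw: Optional[float] = None
    kcats: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.concentration is not None and self.concentration < 0:
            raise ValueError(
                f"protein {self.id}: concentration must be >= 0, "
                f"got {self.concentration}"
            )
        if self.mw is not None and self.mw <= 0:
            raise ValueError(f"protein {self.id}: mw must be > 0, got {self.mw}")
        for rxn_id, kcat in self.kcats.items():
            if kcat <= 0:
                raise ValueError(
                    f"protein {self.id}: kcat for {rxn_id} must be > 0, got {kcat}"
                )


@dataclass
class PoolConstraint:
    """Aggregate enzyme-mass budget ``sum mw_p * supply_p <= total`` (g/gDW)."""

    total: float
    protein_ids: frozenset[str]


@dataclass
class MatchReport:
    """Ids matched/unmatched when mapping measurements onto model enzymes."""

    matched: list[str]
    unmatched: list[str]


class ECModel:
    """A cobra model extended with enzyme rows and supply pseudoexchanges.

    The wrapped :class:`cobra.Model` holds metabolites, reactions, bounds and
    the objective; enzymes live in :attr:`proteins` and are realized in the
    solver as one equality row per enzyme plus one metabolite-free supply
    reaction named ``<protein_id>_supply``.
    """

    def __init__(self, model: Optional[cobra.Model] = None, name: str = "ec_model"):
        self.model: cobra.Model = model if model is not None else cobra.Model(name)
        self.proteins: dict[str, Protein] = {}
        self.pool: Optional[PoolConstraint] = None

    # -- passthrough conveniences -------------------------------------------------
    @property
    def reactions(self):
        return self.model.reactions

    @property
    def metabolites(self):
        return self.model.metabolites

    @property
    def objective(self):
        return self.model.objective

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ECModel {self.model.id!r} reactions={len(self.model.reactions)} "
            f"metabolites={len(self.model.metabolites)} proteins={len(self.proteins)}>"
        )

    # -- solver plumbing ----------------------------------------------------------
    def supply_reaction(self, protein_id: str) -> cobra.Reaction:
        """The pseudoexchange supplying ``protein_id``."""
        return self.model.reactions.get_by_id(protein_id + _SUPPLY_SUFFIX)

    def balance_constraint(self, protein_id: str):
        """The solver equality row balancing supply against usage."""
        return self.model.solver.constraints[protein_id + _BALANCE_SUFFIX]

    def _new_protein(self, protein: Protein) -> None:
        supply = cobra.Reaction(protein.id + _SUPPLY_SUFFIX)
        supply.lower_bound = 0.0
        ub = protein.concentration
        supply.upper_bound = DEFAULT_SUPPLY_UB if ub is None else ub
        self.model.add_reactions([supply])
        row = self.model.problem.Constraint(
            -supply.forward_variable,
            lb=0.0,
            ub=0.0,
            name=protein.id + _BALANCE_SUFFIX,
        )
        self.model.add_cons_vars([row])
        self.model.solver.update()
        self.proteins[protein.id] = protein

    # -- construction -------------------------------------------------------------
    def add_protein(
        self,
        reaction_id: str,
        protein: Protein | str,
        kcat: float,
        *,
        kcat_unit: str = "1/h",
    ) -> "ECModel":
        """Attach an enzyme to a reaction with the given turnover number.

        The reaction gains the enzyme pseudometabolite with coefficient
        ``-1/kcat``; the enzyme's supply pseudoexchange is created on first
        use with bounds ``[0, concentration or DEFAULT_SUPPLY_UB]``.

        Parameters
        ----------
        reaction_id
            Id of an existing (catalyzed) reaction.
        protein
            A :class:`Protein` or a bare id.  If the id is already
            registered, the existing entry is reused.
        kcat
            Turnover number, strictly positive.
        kcat_unit
            ``"1/h"`` (internal storage unit) or ``"1/s"`` (converted on
            ingestion, GECKO convention).
        """
        if kcat_unit == "1/s":
            kcat = kcat * _S_PER_H
        elif kcat_unit != "1/h":
            raise ValueError(f"unknown kcat unit {kcat_unit!r}")
        if not kcat > 0:
            raise ValueError(f"kcat must be > 0, got {kcat}")
        try:
            rxn = self.model.reactions.get_by_id(reaction_id)
        except KeyError:
            raise ValueError(f"unknown reaction id {reaction_id!r}") from None

        if isinstance(protein, str):
            protein = self.proteins.get(protein, Protein(protein))
        if protein.id in self.proteins:
            protein = self.proteins[protein.id]
        else:
            # register with a private kcat map; entries added below
            protein = Protein(protein.id, protein.concentration, protein.mw, {})
            self._new_protein(protein)
        if reaction_id in protein.kcats:
            raise ValueError(
                f"protein {protein.id} already attached to reaction "
                f"{reaction_id}; remove it first to replace the kcat"
            )
        protein.kcats[reaction_id] = kcat
        coef = 1.0 / kcat
        self.balance_constraint(protein.id).set_linear_coefficients(
            {rxn.forward_variable: coef, rxn.reverse_variable: coef}
        )
        return self

    def remove_protein_from_reaction(self, protein_id: str, reaction_id: str) -> None:
        """Detach an enzyme from one reaction (kcat entry and solver term)."""
        protein = self.proteins[protein_id]
        if reaction_id not in protein.kcats:
            raise ValueError(f"{protein_id} is not attached to {reaction_id}")
        rxn = self.model.reactions.get_by_id(reaction_id)
        self.balance_constraint(protein_id).set_linear_coefficients(
            {rxn.forward_variable: 0.0, rxn.reverse_variable: 0.0}
        )
        del protein.kcats[reaction_id]

    # -- bounds -------------------------------------------------------------------
    def protein_bound(self, protein_id: str) -> float:
        return self.supply_reaction(protein_id).upper_bound

    def set_protein_bound(self, protein_id: str, ub: float) -> None:
        if ub < 0:
            raise ValueError("protein supply upper bound must be >= 0")
        self.supply_reaction(protein_id).upper_bound = ub

    def limit_proteins(self, measurements: Mapping[str, float]) -> MatchReport:
        """Set supply upper bounds from measured concentrations (mmol/gDW).

        Matched enzymes get ``ub = measurement`` (and the concentration is
        recorded); ids absent from the model are reported, not an error.
        """
        for pid, value in measurements.items():
            if value < 0:
                raise ValueError(f"negative measurement for {pid}: {value}")
        matched, unmatched = [], []
        for pid, value in measurements.items():
            if pid in self.proteins:
                self.proteins[pid].concentration = value
                self.set_protein_bound(pid, value)
                matched.append(pid)
            else:
                unmatched.append(pid)
        return MatchReport(matched=matched, unmatched=unmatched)

    def release_protein_bounds(self, protein_ids: Optional[Iterable[str]] = None) -> None:
        """Reset supply upper bounds to the default (unbounded) value."""
        ids = list(protein_ids) if protein_ids is not None else list(self.proteins)
        for pid in ids:
            self.set_protein_bound(pid, DEFAULT_SUPPLY_UB)

    def constrain_pool(
        self,
        total: float,
        protein_ids: Optional[Iterable[str]] = None,
        *,
        keep_concentrations: bool = False,
    ) -> "ECModel":
        """Impose the aggregate budget ``sum mw_p * supply_p <= total`` (g/gDW).

        Pooled enzymes without an explicit concentration (or all pooled
        enzymes unless ``keep_concentrations``) have their individual bounds
        released to the pool.  If an enzyme keeps a concentration, the
        effective bound is the tighter of the two (individual and pool).
        """
        if total < 0:
            raise ValueError("pool total must be >= 0")
        ids = sorted(protein_ids) if protein_ids is not None else sorted(self.proteins)
        missing = [p for p in ids if self.proteins[p].mw is None]
        if missing:
            raise ValueError(
                "pooled proteins need a molecular weight (g/mmol); missing for: "
                + ", ".join(missing)
            )
        if _POOL_CONSTRAINT_ID in self.model.solver.constraints:
            self.model.remove_cons_vars(
                [self.model.solver.constraints[_POOL_CONSTRAINT_ID]]
            )
        coeffs = {}
        for pid in ids:
            coeffs[self.supply_reaction(pid).forward_variable] = self.proteins[pid].mw
            if not (keep_concentrations and self.proteins[pid].concentration is not None):
                self.set_protein_bound(pid, DEFAULT_SUPPLY_UB)
        row = self.model.problem.Constraint(0, lb=None, ub=total, name=_POOL_CONSTRAINT_ID)
        self.model.add_cons_vars([row])
        self.model.solver.update()
        row.set_linear_coefficients(coeffs)
        self.pool = PoolConstraint(total=total, protein_ids=frozenset(ids))
        return self

    # -- copying ------------------------------------------------------------------
    def copy(self) -> "ECModel":
        """Deep copy; enzyme rows and the pool constraint are carried over."""
        new = ECModel.__new__(ECModel)
        new.model = self.model.copy()
        new.proteins = {
            pid: Protein(p.id, p.concentration, p.mw, dict(p.kcats))
            for pid, p in self.proteins.items()
        }
        new.pool = (
            None
            if self.pool is None
            else PoolConstraint(self.pool.total, self.pool.protein_ids)
        )
        return new

    # -- introspection ------------------------------------------------------------
    def protein_usage(self, protein_id: str, fluxes: Mapping[str, float]) -> float:
        """Total enzyme demand ``sum_j |v_j| / kcat`` for a flux vector."""
        p = self.proteins[protein_id]
        return sum(abs(fluxes[rid]) / k for rid, k in p.kcats.items())

    def is_protein_supply(self, reaction_id: str) -> bool:
        return (
            reaction_id.endswith(_SUPPLY_SUFFIX)
            and reaction_id[: -len(_SUPPLY_SUFFIX)] in self.proteins
        )


# -- module-level functional aliases (operate in place, return the model) ----------

def add_protein(
    model: ECModel, reaction_id: str, protein: Protein | str, kcat: float, **kw
) -> ECModel:
    """Functional alias for :meth:`ECModel.add_protein`."""
    return model.add_protein(reaction_id, protein, kcat, **kw)


def constrain_pool(
    model: ECModel, total: float, protein_ids: Optional[Iterable[str]] = None, **kw
) -> ECModel:
    """Functional alias for :meth:`ECModel.constrain_pool`."""
    return model.constrain_pool(total, protein_ids, **kw)


def limit_proteins(model: ECModel, measurements: Mapping[str, float]) -> MatchReport:
    """Functional alias for :meth:`ECModel.limit_proteins`."""
    return model.limit_proteins(measurements)
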
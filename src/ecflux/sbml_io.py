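"""SBML persistence of enzyme-constrained models.

Enzymes are serialized as plain SBML ``Species`` collected in a groups
package group with id ``"Protein"`` — the document is self-contained and no
naming convention is needed to tell enzymes from metabolites:

* the optional species attribute ``initialAmount`` carries the measured
  concentration (mmol/gDW, the unit of the supply bound it maps onto);
* turnover numbers appear only as reaction stoichiometries: an enzyme
  consumed with coefficient ``1/kcat``;
* each enzyme is produced by its supply pseudoexchange, whose flux bounds
  are ordinary FBC bounds.

A legacy dialect is also read: species named ``prot_<ACCESSION>``, reversible
reactions split into ``<id>``/``<id>_REV`` pairs (merged back into one
reversible reaction on read) and ``arm_`` isozyme constructs (kept as-is,
flagged).  Molecular weights, which SBML has no numeric slot for, ride in
the species notes as ``mw_g_per_mmol: <value>``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
import cobra
import libsbml

from .ec_model import DEFAULT_SUPPLY_UB, ECModel, Protein

__all__ = ["SbmlDialect", "read_model", "write_model", "GROUPS_NS"]

GROUPS_NS = "http://www.sbml.org/sbml/level3/version1/groups/version1"
PROTEIN_GROUP_ID = "Protein"
MEMBER_LIST_ID = "all_proteins"

_REV_SUFFIX = re.compile(r"^(?P<base>.+)_REV(?:No\d+)?$")
_MW_NOTE = re.compile(r"mw_g_per_mmol:\s*([0-9.eE+-]+)")


@dataclass
class SbmlDialect:
    """How enzymes were encoded in a document that was read."""

    mode: str  # "group-based" | "legacy-naming" | "plain"
    markers: list[str] = field(default_factory=list)


class SbmlParseError(ValueError):
    """The document violates the enzyme-group conventions."""


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _scan_document(path: str):
    """libsbml pass: group members, initialAmounts, mw notes."""
    doc = libsbml.readSBML(path)
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise SbmlParseError(doc.getError(0).getMessage())
    model = doc.getModel()
    if model is None:
        raise SbmlParseError(f"no SBML model in {path}")
    species_ids = {model.getSpecies(i).getId() for i in range(model.getNumSpecies())}
    amounts: dict[str, float] = {}
    mws: dict[str, float] = {}
    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        if sp.isSetInitialAmount():
            if sp.getInitialAmount() < 0:
                raise SbmlParseError(
                    f"species {sp.getId()} has negative initialAmount"
                )
            amounts[sp.getId()] = sp.getInitialAmount()
        if sp.isSetNotes():
            m = _MW_NOTE.search(sp.getNotesString())
            if m:
                mws[sp.getId()] = float(m.group(1))
    group_members: list[str] = []
    has_group = False
    gplug = model.getPlugin("groups")
    if gplug is not None:
        for gi in range(gplug.getNumGroups()):
            group = gplug.getGroup(gi)
            if group.getId() == PROTEIN_GROUP_ID or group.getName() == PROTEIN_GROUP_ID:
                has_group = True
                for mi in range(group.getNumMembers()):
                    member = group.getMember(mi)
                    ref = member.getIdRef()
                    if not ref:
                        raise SbmlParseError(
                            f"group {PROTEIN_GROUP_ID!r} has a member without idRef"
                        )
                    if ref not in species_ids:
                        raise SbmlParseError(
                            f"group member {ref!r} is not in listOfSpecies"
                        )
                    group_members.append(ref)
    return group_members, has_group, amounts, mws


def _cobra_metabolite_id(model: cobra.Model, sbml_id: str):
    """Map an SBML species id to cobra's (possibly M_-stripped) metabolite."""
    for candidate in (sbml_id, sbml_id[2:] if sbml_id.startswith("M_") else None):
        if candidate and candidate in model.metabolites:
            return model.metabolites.get_by_id(candidate)
    return None


def _merge_split_reactions(model: cobra.Model, markers: list[str]) -> None:
    """Collapse legacy ``<id>/<id>_REV`` pairs into reversible reactions."""
    to_remove = []
    for rxn in list(model.reactions):
        m = _REV_SUFFIX.match(rxn.id)
        if not m:
            continue
        base_id = m.group("base")
        if base_id not in model.reactions:
            continue
        base = model.reactions.get_by_id(base_id)
        base.lower_bound = -rxn.upper_bound
        to_remove.append(rxn)
        markers.append(f"merged split pair {base_id}/{rxn.id}")
    if to_remove:
        model.remove_reactions(to_remove)


def read_model(path) -> ECModel:
    """Read an SBML L3/FBC document into an :class:`ECModel`.

    Both the group-based dialect and the legacy ``prot_`` naming dialect
    are understood; the detected dialect is attached as ``model.dialect``.
    """
    path = str(path)
    group_members, has_group, amounts, mws = _scan_document(path)
    cobra_model = cobra.io.read_sbml_model(path)

    markers: list[str] = []
    protein_ids: dict[str, str] = {}  # cobra metabolite id -> protein id
    if has_group:
        mode = "group-based"
        markers.append(f"group {PROTEIN_GROUP_ID!r} with {len(group_members)} members")
        for ref in group_members:
            met = _cobra_metabolite_id(cobra_model, ref)
            if met is None:
                raise SbmlParseError(
                    f"protein species {ref!r} not readable as a model species"
                )
            protein_ids[met.id] = ref if not ref.startswith("M_") else ref[2:]
    else:
        legacy = [m for m in cobra_model.metabolites if m.id.startswith("prot_")]
        if legacy:
            mode = "legacy-naming"
            for met in legacy:
                accession = met.id[len("prot_"):]
                protein_ids[met.id] = accession
                markers.append(f"legacy species {met.id}")
        else:
            mode = "plain"

    for rxn in cobra_model.reactions:
        if rxn.id.startswith("arm_"):
            markers.append(f"legacy arm reaction {rxn.id} (kept as-is)")

    if mode == "legacy-naming":
        _merge_split_reactions(cobra_model, markers)

    # harvest kcats / supply bounds, then strip protein species from cobra
    ec = ECModel(cobra_model)
    pending = []  # (protein, [(rxn_id, kcat)], supply_bounds)
    supply_rxns = []
    for met_id, pid in sorted(protein_ids.items()):
        met = cobra_model.metabolites.get_by_id(met_id)
        sbml_id = met_id  # id as it appeared for amounts lookup
        kcats = []
        supply_bounds = None
        for rxn in sorted(met.reactions, key=lambda r: r.id):
            coef = rxn.metabolites[met]
            if coef < 0:
                # stoichiometry stores 1/kcat; snap the reciprocal to 10
                # significant digits so kcats written with ordinary decimal
                # precision survive the double->text->double round trip
                kcats.append((rxn.id, float(f"{-1.0 / coef:.10g}")))
            elif len(rxn.metabolites) == 1:
                supply_bounds = rxn.bounds
                supply_rxns.append(rxn)
        conc = amounts.get(sbml_id, amounts.get("M_" + sbml_id))
        if conc is None and supply_bounds is not None:
            ub = supply_bounds[1]
            if ub < DEFAULT_SUPPLY_UB:
                conc = ub
        mw = mws.get(sbml_id, mws.get("M_" + sbml_id))
        pending.append((Protein(pid, concentration=conc, mw=mw), kcats))

    for group in list(cobra_model.groups):
        if group.id == PROTEIN_GROUP_ID or group.name == PROTEIN_GROUP_ID:
            cobra_model.remove_groups([group])
    if supply_rxns:
        cobra_model.remove_reactions(supply_rxns)
    if protein_ids:
        mets = [cobra_model.metabolites.get_by_id(mid) for mid in protein_ids]
        cobra_model.remove_metabolites(mets, destructive=False)

    for protein, kcats in pending:
        for rxn_id, kcat in kcats:
            ec.add_protein(rxn_id, protein, kcat)
            protein = ec.proteins[protein.id]
        if not kcats:
            # enzyme declared but unused by any reaction: register anyway
            ec._new_protein(protein)
        if protein.concentration is not None:
            ec.set_protein_bound(protein.id, protein.concentration)

    ec.dialect = SbmlDialect(mode=mode, markers=markers)
    return ec


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def _protein_compartment(ec: ECModel, protein: Protein) -> str:
    for rxn_id in sorted(protein.kcats):
        rxn = ec.model.reactions.get_by_id(rxn_id)
        for met in sorted(rxn.metabolites, key=lambda m: m.id):
            if met.compartment:
                return met.compartment
    return next(iter(ec.model.compartments), None) or "c"


def write_model(ec: ECModel, path) -> None:
    """Write an :class:`ECModel` as a self-contained group-based document.

    ``read_model(write_model(m))`` reproduces proteins, concentrations,
    kcats, bounds and the objective exactly.  Models without enzymes yield
    a plain SBML document with no group.
    """
    path = str(path)
    cobra.io.write_sbml_model(ec.model, path)
    if not ec.proteins:
        return
    doc = libsbml.readSBML(path)
    model = doc.getModel()
    doc.enablePackage(GROUPS_NS, "groups", True)
    doc.setPackageRequired("groups", False)
    gplug = model.getPlugin("groups")
    group = gplug.createGroup()
    group.setId(PROTEIN_GROUP_ID)
    group.setKind("classification")

    for pid in sorted(ec.proteins):
        protein = ec.proteins[pid]
        comp = _protein_compartment(ec, protein)
        if model.getCompartment(comp) is None:
            c = model.createCompartment()
            c.setId(comp)
            c.setConstant(True)
        sp = model.createSpecies()
        sp.setId(pid)
        sp.setCompartment(comp)
        sp.setConstant(False)
        sp.setBoundaryCondition(False)
        sp.setHasOnlySubstanceUnits(False)
        if protein.concentration is not None:
            sp.setInitialAmount(protein.concentration)
        if protein.mw is not None:
            sp.setNotes(
                f'<body xmlns="http://www.w3.org/1999/xhtml">'
                f"<p>mw_g_per_mmol: {protein.mw!r}</p></body>"
            )
        for rxn_id, kcat in sorted(protein.kcats.items()):
            rxn = model.getReaction("R_" + rxn_id) or model.getReaction(rxn_id)
            sr = rxn.createReactant()
            sr.setSpecies(pid)
            sr.setStoichiometry(1.0 / kcat)
            sr.setConstant(True)
        supply_id = f"{pid}_supply"
        supply = model.getReaction("R_" + supply_id) or model.getReaction(supply_id)
        sr = supply.createProduct()
        sr.setSpecies(pid)
        sr.setStoichiometry(1.0)
        sr.setConstant(True)
        member = group.createMember()
        member.setIdRef(pid)
    group.getListOfMembers().setId(MEMBER_LIST_ID)
    libsbml.writeSBMLToFile(doc, path)
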
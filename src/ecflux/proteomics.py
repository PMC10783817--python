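"""Conversion of quantitative proteomics to enzyme supply bounds.

Absolute proteomics reports an intensity ``I_i`` per protein; together with
the molecular mass ``mu_i`` (g/mmol, numerically kDa) this gives the mass
fraction

    phi_i = mu_i * I_i / sum_k mu_k * I_k

which is converted to mmol/gDW via the cell-volume chain

    mmol/um^3 = phi_i * 13.5e-8 [ug/um^3] * 1e-6 [g/ug] * 1000 / mu_i
    mmol/gDW  = mmol/um^3 * X [um^3/(OD*mL)] / 320 [ug protein/(OD*mL)]
                * 1e6 [ug/g] * 0.448 [g protein/gDW]
    X         = -0.3e9 * GR + 2.83e9

where ``GR`` is the growth rate (1/h), ``13.5e-8 ug/um^3`` the cellular
protein density, ``320 ug/(OD*mL)`` the protein content per optical
density for E. coli, and ``0.448 g protein/gDW`` the protein fraction of
dry weight (an empirical constant, overridable per condition).  The
``1000`` factor converts mol to mmol given ``mu`` in g/mmol.

``build_condition`` assembles a per-condition model: records are converted
and applied as supply bounds, uptake bounds set, growth fixed to the chosen
confidence-interval limit capped at the model's enzyme-free FBA optimum,
and declarative edits (gene/reaction knockouts) applied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from cobra.util.solver import linear_reaction_coefficients

from .ec_model import ECModel, MatchReport
from .exceptions import InfeasibleError

__all__ = [
    "ProteomicsRecord",
    "ConversionParams",
    "ConditionReport",
    "mass_fractions",
    "cell_volume",
    "phi_to_mmol_gdw",
    "convert_records",
    "read_proteomics_table",
    "build_condition",
]

logger = logging.getLogger(__name__)


@dataclass
class ProteomicsRecord:
    """One protein's quantification: intensity, molecular mass, mass fraction."""

    protein_id: str
    intensity: float
    mw: float  # g/mmol (= kDa)
    phi: Optional[float] = None  # mass fraction in [0, 1]

    def __post_init__(self) -> None:
        if self.intensity < 0:
            raise ValueError(f"{self.protein_id}: negative intensity")
        if self.mw <= 0:
            raise ValueError(f"{self.protein_id}: molecular mass must be > 0")
        if self.phi is not None and not 0 <= self.phi <= 1:
            raise ValueError(f"{self.protein_id}: phi must be in [0, 1]")


@dataclass
class ConversionParams:
    """Constants of the intensity -> mmol/gDW chain (E. coli defaults)."""

    density_const: float = 13.5e-8  # ug/um^3
    protein_per_odml: float = 320.0  # ug/(OD*mL)
    protein_gdw_frac: float = 0.448  # g protein/gDW
    volume_slope: float = -0.3e9  # um^3/(OD*mL) per (1/h)
    volume_intercept: float = 2.83e9  # um^3/(OD*mL)


@dataclass
class ConditionReport:
    """What happened while constraining a model to one condition."""

    match: MatchReport
    growth_bound: float
    growth_capped: bool
    knockouts: list[str] = field(default_factory=list)


def mass_fractions(
    records: Iterable[tuple[str, float, float] | ProteomicsRecord],
) -> list[ProteomicsRecord]:
    """Compute mass fractions ``phi_i = mu_i I_i / sum mu_k I_k``.

    Accepts ``(protein_id, intensity, mw)`` tuples or records; the returned
    records carry ``phi`` and the fractions sum to one.
    """
    recs = [
        r if isinstance(r, ProteomicsRecord) else ProteomicsRecord(*r)
        for r in records
    ]
    total = sum(r.mw * r.intensity for r in recs)
    if not total > 0:
        raise ValueError("all intensities are zero; mass fractions undefined")
    return [replace(r, phi=r.mw * r.intensity / total) for r in recs]


def cell_volume(growth_rate: float, params: ConversionParams = ConversionParams()) -> float:
    """Cellular volume per OD*mL, ``X = slope * GR + intercept`` (um^3/(OD*mL))."""
    if growth_rate < 0:
        raise ValueError("growth rate must be >= 0")
    x = params.volume_slope * growth_rate + params.volume_intercept
    if x <= 0:
        raise ValueError(
            f"growth rate {growth_rate} gives non-positive cell volume {x}"
        )
    return x


def phi_to_mmol_gdw(
    record: ProteomicsRecord | float,
    growth_rate: float,
    params: ConversionParams = ConversionParams(),
    *,
    mw: Optional[float] = None,
) -> float:
    """Convert a mass fraction to mmol/gDW at the given growth rate.

    ``record`` may be a :class:`ProteomicsRecord` (with ``phi`` set) or a
    bare ``phi`` value together with ``mw``.
    """
    if isinstance(record, ProteomicsRecord):
        phi, mu = record.phi, record.mw
        if phi is None:
            raise ValueError(f"{record.protein_id}: phi not computed")
    else:
        phi, mu = float(record), mw
        if mu is None:
            raise ValueError("mw is required when passing a bare phi")
    if mu <= 0:
        raise ValueError("molecular mass must be > 0")
    x = cell_volume(growth_rate, params)
    mmol_per_um3 = phi * params.density_const * 1e-6 * 1000.0 / mu
    return (
        mmol_per_um3 * x / params.protein_per_odml * 1e6 * params.protein_gdw_frac
    )


def convert_records(
    records: Sequence[ProteomicsRecord],
    growth_rate: float,
    params: ConversionParams = ConversionParams(),
) -> dict[str, float]:
    """Map protein id -> mmol/gDW; computes phi first when absent."""
    if any(r.phi is None for r in records):
        records = mass_fractions(records)
    return {
        r.protein_id: phi_to_mmol_gdw(r, growth_rate, params) for r in records
    }


def read_proteomics_table(path) -> list[ProteomicsRecord]:
    """Read a TSV/CSV with columns ``protein_id``, ``intensity`` (or
    ``phi``) and ``mw_kda``."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    if "protein_id" not in df or "mw_kda" not in df:
        raise ValueError("table needs protein_id and mw_kda columns")
    recs = []
    for row in df.itertuples(index=False):
        phi = getattr(row, "phi", None)
        intensity = getattr(row, "intensity", 0.0)
        recs.append(
            ProteomicsRecord(
                protein_id=str(row.protein_id),
                intensity=float(intensity) if intensity == intensity else 0.0,
                mw=float(row.mw_kda),
                phi=float(phi) if phi is not None and phi == phi else None,
            )
        )
    return recs


def _objective_reaction(ec: ECModel):
    rxns = list(linear_reaction_coefficients(ec.model))
    if len(rxns) != 1:
        raise ValueError("model needs a single-reaction objective (growth)")
    return ec.model.reactions.get_by_id(rxns[0].id)


def build_condition(
    model: ECModel,
    records: Sequence[ProteomicsRecord],
    growth_rate: float,
    *,
    uptake: Optional[Mapping[str, float]] = None,
    growth_ci: Optional[tuple[float, float]] = None,
    knockouts: Sequence[str] = (),
    params: ConversionParams = ConversionParams(),
    use_ci_lower_growth: bool = True,
) -> tuple[ECModel, ConditionReport]:
    """Constrain a copy of ``model`` to one experimental condition.

    The growth bound is the lower 95% CI limit when available (upper CI
    limits are used for the concentrations upstream, i.e. in the records'
    intensities), capped at the enzyme-free FBA optimum of the model; uptake
    bounds are magnitudes of consumption (applied to the exchange lower
    bound); knockouts close both directions of the named reactions.

    Raises :class:`InfeasibleError` if the growth bound cannot be met even
    before proteomics is applied (an uptake misconfiguration).
    """
    out = model.copy()
    report_knockouts = []
    for rid in knockouts:
        out.model.reactions.get_by_id(rid).bounds = (0.0, 0.0)
        report_knockouts.append(rid)
    if uptake:
        for ex_id, bound in uptake.items():
            ex = out.model.reactions.get_by_id(ex_id)
            ex.lower_bound = -abs(bound)

    # enzyme-free optimum: protein bounds released on a probe copy
    probe = out.copy()
    probe.release_protein_bounds()
    unconstrained_opt = probe.model.slim_optimize()
    if unconstrained_opt != unconstrained_opt:  # NaN
        raise InfeasibleError(
            "model infeasible before proteomics; check uptake bounds"
        )
    target = growth_rate
    if growth_ci is not None:
        target = growth_ci[0] if use_ci_lower_growth else growth_ci[1]
    capped = target > unconstrained_opt
    if capped:
        logger.warning(
            "growth bound %.6g exceeds the enzyme-free optimum %.6g; capping",
            target,
            unconstrained_opt,
        )
        target = unconstrained_opt
    growth_rxn = _objective_reaction(out)
    growth_rxn.bounds = (target, target)

    converted = convert_records(records, growth_rate, params)
    match = out.limit_proteins(converted)
    return out, ConditionReport(
        match=match,
        growth_bound=target,
        growth_capped=capped,
        knockouts=report_knockouts,
    )
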
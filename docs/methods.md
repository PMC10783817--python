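# Methods

## Model formulation

An enzyme-constrained model extends a stoichiometric model `S v = 0,
lb <= v <= ub` with one equality row per enzyme and one supply
pseudoexchange column per enzyme.  Enzyme `p` catalyzing reaction `j`
with turnover number `kcat_{p,j}` (1/h) contributes `v_j / kcat_{p,j}` to
the row

    -supply_p + sum_{j in p} v_j / kcat_{p,j} = 0 ,

so `supply_p` (mmol/gDW) is exactly the enzyme amount the flux state
demands, and the supply upper bound — the measured concentration, or the
default 1000 mmol/gDW/h when unmeasured — enforces `v_j <= kcat * supply_p`.
Enzyme complexes are modeled by attaching each subunit to the same
reaction with its own `kcat`; isozymes (OR relationships) are outside the
construction API, though legacy documents that encode them as duplicated
reactions still load.

Reversible catalyzed reactions are handled inside the solver layer:
the enzyme row sums the solver's forward *and* reverse flux variables, so
usage is charged `|v_j| / kcat` without splitting the reaction in the
persisted document.  This is why the rows are maintained as explicit
solver constraints rather than as metabolite rows of the stoichiometric
matrix (a metabolite row would credit enzyme back on reverse flux).

Turnover numbers are stored internally in 1/h; the ingestion boundary
accepts 1/s (`kcat_unit="1/s"`, multiplied by 3600), since kinetic
databases report per-second values while genome-scale models use hours.

### Protein pool

`constrain_pool(total, ids)` adds `sum_p mw_p * supply_p <= total`
(g protein/gDW) over the pooled enzymes and releases their individual
bounds to the pool.  An enzyme may keep an explicit concentration while
pooled (`keep_concentrations=True`); the effective bound is then the
tighter of the two constraints.  This coexistence semantics is our
choice; the formulations in the literature do not pin it down.

## SBML persistence

Enzymes are ordinary `Species` collected in a groups-package group with
id `"Protein"` (kind `classification`, member list id `all_proteins`):

* `initialAmount` (optional) carries the concentration, interpreted in
  mmol/gDW — the unit of the supply bound it maps onto;
* `1/kcat` appears as the reactant stoichiometry of the catalyzed
  reaction; the supply pseudoexchange produces the species with
  stoichiometry 1 and ordinary FBC flux bounds;
* the enzyme's compartment is that of the first metabolite of its first
  catalyzed reaction (SBML requires species to have one).

Molecular weights have no numeric slot in SBML; they are written into the
species notes as `mw_g_per_mmol: <value>`, a key–value notes convention
as used by COBRA tooling.

Legacy dialects are detected and normalized on read: species named
`prot_<ACCESSION>` become enzymes, `<id>`/`<id>_REV` pairs are merged into
one reversible reaction (`lb = -ub_REV`), and `arm_`-prefixed isozyme
constructs are kept as-is but flagged in the dialect report.  The supply
exchange's upper bound doubles as the concentration when no
`initialAmount` is present and the bound is below the default.

**Numerical round trip.**  Writing a kcat as the double `1/kcat` and
re-reading `−1/coefficient` cannot reproduce the original bit pattern in
general (the reciprocal map is not invertible in IEEE doubles, and the
XML layer prints ~15 significant digits).  The reader therefore snaps
recovered kcats to 10 significant digits, which makes the round trip
exact for any kcat specified with ordinary decimal precision; the
fixture generators emit kcats with at most 6 significant digits and
bounds with at most 9.  The pool constraint is a solver-level entity and
is not persisted to SBML.

## Relaxation algorithms

All methods first check feasibility (empty result if feasible) and work
on a copy; they raise a dedicated error when relaxing every targeted
enzyme row still leaves the problem infeasible, which signals a conflict
in non-enzyme constraints (growth or uptake bounds).

* **Elastic filtering LP.**  Per targeted row an elastic variable
  `e in [0, 1000]` enters as extra supply; the LP minimizes `sum e`
  (or `-Z + sum e` with the original objective included, both terms with
  unit weight).  Elastics with primal above 1e-7 are recorded into the
  IIS, dropped from the objective (kept free — the alternative of fixing
  them at their primal values would make later iterations conservative),
  and the LP is re-solved until no new elastic activates.  Only the
  upper direction is elasticized because enzyme supplies have zero lower
  bounds.
* **Minimal-cardinality MILP.**  Per row a binary `i` and a continuous
  compensation `l in [0, K]` enter as `-K i + l` with `K = 1000`, large
  enough to dominate any supply; minimizing `sum i` counts relaxed
  enzymes.  Because relaxation is only ever needed in the upper
  direction, this stays linear (no quadratic complementarity).  The
  optimal set need not be unique, so tests validate feasibility and
  minimal cardinality (against brute-force subset enumeration), not set
  identity.  An `expand=True` variant iterates like the elastic filter,
  accumulating binaries dropped from the objective.
* **Greedy shadow-price removal.**  Iteratively solve FBA (with the
  objective reaction's lower bound released so the problem is
  optimizable), rank bounded enzymes by the reduced cost of their supply
  variable — the marginal objective gain per unit of extra enzyme — and
  unbound the top one (ties broken lexicographically by id for
  reproducibility) until the target growth is reached.  Capped at one
  removal per enzyme; exhausting all enzymes raises a distinct error.

**Thresholds.**  IIS membership uses the 1e-7 primal threshold (the LP
solvers' numerical noise floor) for *reporting*; the applied relaxation
values keep every positive primal (floor 1e-12), because discarding
sub-threshold slack can leave the "relaxed" model marginally infeasible
under a solver with tighter tolerances.  `apply_relaxation` adds a 1e-9
cushion to each raised bound for the same reason.

## Flux analysis

* **FBA** returns the optimum, fluxes, per-enzyme supplies and, for pure
  LPs, the supply reduced costs used by the greedy method.  Infeasible
  and unbounded statuses raise distinct exceptions.
* **FVA** fixes the objective at a fraction of its optimum (default 1.0),
  optionally pins a named uptake exchange at its minimal consumption
  inside the optimal space first (so variability is compared at equal
  substrate usage), then minimizes/maximizes each reaction.  With
  `block_opposite_split` the `_REV` counterpart of a legacy split pair
  is bounded to zero while its partner is scanned, removing the spurious
  two-way variability such pairs otherwise show.  GLPK's simplex is
  deterministic, so repeated scans give identical tables.
* **Average saturation** is the mean of `supply_p / ub_p` over enzymes
  with an explicit non-zero bound (enzymes at the default unbounded
  supply are not meaningfully saturable and are excluded); `active_only`
  restricts to enzymes with supply above 1e-7.

## Thermodynamic layer

For each reaction with a standard transformed Gibbs energy `dG'0`
(kJ/mol), the transformed energy is `dG' = dG'0 + RT sum_i s_i ln c_i`
with log-concentration variables bounded by per-metabolite ranges
(default ln 1e-6 to ln 0.02 molar, the span conventionally assumed for
cytosolic metabolites).  Binary direction variables and a big-M constant
couple flux sign to the sign of `dG'`:

    v_fwd <= M z_f        dG' <= -delta + M (1 - z_f)
    v_rev <= M z_b       -dG' <= -delta + M (1 - z_b)
    z_f + z_b <= 1

with `M = 1000` (validated to dominate every flux bound) and a minimum
driving force `delta = 1e-3` kJ/mol to break the `dG' = 0` degeneracy.
Reactions without `dG'0` receive no constraint; already-irreversible
reactions keep their direction (their reverse variable is fixed at zero
anyway).

### Layered FVA comparison

`layered_fva` compares combinations of constraint layers (thermo,
proteomics, pool) at one *common* growth: the optimum of the
thermo-constrained model when a thermo layer is requested, otherwise the
smallest optimum across the requested combinations.  A shared growth
bound is what makes the per-reaction intervals of nested constraint sets
themselves nested; fixing each combination at its own optimum would
break that.  A combination that cannot reach the common growth because
of its enzyme bounds is relaxed with the minimal-cardinality MILP
followed by a greedy keep-back filter (each IIS member is re-tightened
and kept if the model stays feasible), and the finally removed enzymes
are reported per combination.  Relaxation only targets enzyme bounds; a
pool or thermo conflict with the growth bound raises instead.

## Proteomics conversion

Mass fractions `phi_i = mu_i I_i / sum_k mu_k I_k` are converted to
mmol/gDW through the cell-volume chain documented in
`ecflux.proteomics`, with E. coli defaults: protein density
13.5e-8 ug/um^3, 320 ug protein per OD·mL, protein dry-weight fraction
0.448 g/gDW (an empirical constant, overridable per condition), and the
linear volume fit `X = -0.3e9 GR + 2.83e9` um^3/(OD·mL), valid for
growth rates below ~9.4/h (where X would turn negative; rejected).  The
`1000` factor in the chain converts mol to mmol given molecular weights
in g/mmol (numerically kDa); the density constant is treated as an
opaque calibration constant.  `phi_to_mmol_gdw(1, mw=1, GR)` collapses
to the closed form `1.35e-10 * X(GR) / 320 * 1e6 * 0.448`, which the
test suite checks to 1e-12 relative.

`build_condition` applies a condition: convert records, bound matched
enzymes (data proteins absent from the model are reported and skipped;
model enzymes absent from the data keep their default supply), set
uptake magnitudes on exchange lower bounds, close knocked-out reactions
in both directions, and fix growth to the chosen confidence-interval
limit (lower CI by default) capped at the model's enzyme-free optimum —
a growth demand above what the stoichiometry allows would otherwise make
every condition trivially infeasible for non-enzyme reasons.

## Synthetic fixtures

`make_toy_ec_model` builds the four-metabolite chain `A + 2B -> C`,
`A + C -> 4D` with exchanges (A up to 10, B up to 20), D export as
objective (plain optimum 20), enzymes P1 (kcat 10/h, mw 10) and P2
(kcat 20/h, mw 25), plus optional seeded independent branches
`S_i -> D`, each with its own exchange (ub 2–8), enzyme, kcat (5–50/h)
and mw (5–50 g/mmol).  Because every branch is saturated at the optimum,
each branch enzyme's required supply is uniquely determined — the
property that makes ground-truth recovery tests of the relaxation
algorithms exact.

`make_infeasible_case` draws enzymes active at the optimum, cuts their
bounds to `required * (1 - magnitude)` (relative reduction in (0, 1];
zero is rejected because the model would stay feasible), pins the
objective at the pre-tightening optimum, verifies infeasibility, and
returns the ground-truth violated set.

`make_core_ec_model` decorates the bundled E. coli core network
(95 reactions, 72 metabolites) with 55 synthetic enzymes on seeded
gene-associated internal reactions; kcats are log-uniform in
[1e3, 1e6] 1/h — centered near the ~10/s median of measured turnover
numbers — and molecular weights uniform in [20, 100] g/mmol.  It is a
synthetic stand-in emulating curated enzyme-constrained core models, not
a reconstruction: enzyme–reaction assignments, kcats and weights are
draws, so only structural counts and generic behavior (growth unchanged
while enzymes are unbounded, relaxation behavior under measured bounds)
carry over to real models.  What the passing tests show is that the
algorithms are correct on networks of this shape; they do not validate
any organism-specific kinetic parameterization.

## Verification strategy and problem sizes

The acceptance pipeline (also `scripts/acceptance.py`) uses 50 seeded
infeasible fixtures (toy + 3 branches, 1–3 violations) for the
feasibility-restoration and minimality checks — sizes at which
brute-force subset enumeration (≤ 2^5 solves per case) and an
independent all-slack LP built with scipy/HiGHS from the raw model
structure are exact oracles against the GLPK implementation path — and
a 10-condition synthetic benchmark on the core model for the
relaxation-vs-growth correlation.  These sizes keep the full pipeline
under a minute while leaving every oracle exhaustive rather than
sampled.

## Known limitations

* Isozyme (OR) semantics are not modeled; each enzyme–reaction pair is
  independent.
* The pool constraint and enzyme molecular weights live outside the SBML
  core (solver layer and species notes, respectively).
* FVA on thermo-constrained models solves one MILP per scan direction;
  fine for core-scale models, slow at genome scale.
* The greedy method needs an optimizable problem; models made infeasible
  by fixed non-objective bounds are rejected with guidance to use the
  LP/MILP methods.
* Shadow-price ties in the greedy ranking are broken by id, which is
  reproducible but arbitrary when duals are degenerate.
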
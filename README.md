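# ecflux

Enzyme-constrained metabolic modeling for the constraint-based modeling
community: build GECKO-style models on top of
[cobrapy](https://opencobra.github.io/cobrapy/), store them as
self-contained SBML documents, convert absolute proteomics into enzyme
supply bounds, reconcile infeasible models with a suite of LP/MILP
relaxation algorithms, and compare constraint layers (enzymes, proteomics,
protein pool, thermodynamics) with enzyme-aware flux analysis.

## The problem

Flux balance analysis (FBA) predicts steady-state fluxes of a metabolic
network by solving

```
maximize    Z = c'v
subject to  S v = 0
            lb_j <= v_j <= ub_j
```

where `S` is the stoichiometric matrix and `v` the flux vector.  An
enzyme-constrained (EC) model extends `S` with one row per enzyme `p` and
one supply pseudoexchange column per enzyme: an enzyme catalyzing reaction
`j` with turnover number `kcat` (1/h) appears in `j` with stoichiometric
coefficient `-1/kcat`, so any feasible solution satisfies
`v_j <= kcat * supply_p`, and the supply upper bound carries the measured
enzyme concentration (mmol/gDW).  Enzymes without individual measurements
can share a pool budget `sum_p mw_p * supply_p <= total` (g/gDW).

Measured proteomics and growth rates routinely make such models
*infeasible*: some measured enzyme levels cannot carry the required flux.
`ecflux` computes an irreducibly inconsistent set (IIS) of enzyme
constraints and how much each must be violated, by four algorithms:

* **elastic filtering LP** — per targeted enzyme row an elastic variable
  `e in [0, 1000]` acts as extra supply; minimize `sum e`, iterating to
  expand the IIS;
* **elastic filtering with the original objective** — minimize
  `-Z + sum e`;
* **minimal-cardinality MILP** — per row a binary `i` and compensation
  `l in [0, K]` enter as `-K*i + l` (`K = 1000`); minimize `sum i`;
* **greedy shadow-price removal** — iteratively unbound the enzyme whose
  supply bound is most growth-limiting until a target growth is reached.

In the persisted SBML, enzymes are ordinary `Species` collected in a
groups-package group named `"Protein"`, with the concentration in the
optional `initialAmount` attribute and `1/kcat` as the reaction
stoichiometry — no naming conventions.  Legacy encodings (`prot_ACCESSION`
species, `_REV` split reversible reactions) are read and normalized.

## Worked example

```python
import cobra
from ecflux import (ECModel, Protein, fba, elastic_filter,
                    apply_relaxation, average_saturation)

m = cobra.Model("demo")
A, B, C, D = (cobra.Metabolite(x, compartment="c") for x in "ABCD")
def rxn(rid, stoich, lb, ub):
    r = cobra.Reaction(rid); r.bounds = (lb, ub)
    m.add_reactions([r]); r.add_metabolites(stoich); return r
rxn("R1", {A: -1, B: -2, C: 1}, 0, 1000)     # A + 2B -> C
rxn("R2", {A: -1, C: -1, D: 4}, 0, 1000)     # A + C  -> 4D
rxn("EX_A", {A: 1}, 0, 10); rxn("EX_B", {B: 1}, 0, 20)
rxn("EX_D", {D: -1}, 0, 1000)
m.objective = "EX_D"

ec = ECModel(m)
ec.add_protein("R1", Protein("P1", mw=10.0), kcat=10.0)
ec.add_protein("R2", Protein("P2", mw=25.0), kcat=20.0)

print(f"plain optimum: {fba(ec).objective_value:.1f}")
ec.limit_proteins({"P1": 0.3})
sol = fba(ec)
print(f"with P1 <= 0.3 mmol/gDW: {sol.objective_value:.1f}")
print(f"P1 saturation: {average_saturation(ec, sol).overall:.2f}")

ec.model.reactions.EX_D.bounds = (20, 20)    # demand the full export anyway
result = elastic_filter(ec)
print(f"IIS: {sorted(result.iis)}, extra supply needed: "
      f"{result.relaxation_values['P1']:.3f} mmol/gDW")
relaxed = apply_relaxation(ec, result)
print(f"after relaxation: {fba(relaxed).objective_value:.1f}")
```

prints

```
plain optimum: 20.0
with P1 <= 0.3 mmol/gDW: 12.0
P1 saturation: 1.00
IIS: ['P1'], extra supply needed: 0.200 mmol/gDW
after relaxation: 20.0
```

Reading: without enzyme data the network exports 20 units of D; capping P1
at 0.3 mmol/gDW limits R1 to `kcat * 0.3 = 3` and the export to 12, with
P1 fully saturated.  Demanding the export of 20 anyway makes the model
infeasible; the elastic LP identifies P1 as the sole inconsistent
constraint and quantifies the violation (0.2 mmol/gDW, i.e. the required
0.5 minus the measured 0.3), and applying it restores feasibility.

The same operations are available from the shell:

```bash
ecflux fixtures make --seed 0 --p1-concentration 0.3 --out toy.xml
ecflux fba toy.xml
ecflux relax toy.xml --method milp
ecflux convert --data proteomics.tsv --growth-rate 0.5
ecflux fva toy.xml --fix-uptake EX_glc__D_e --block-opposite-split
```

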
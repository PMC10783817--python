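"""Shared fixtures: toy models and hand-written SBML documents."""

import pytest

from ecflux import make_toy_ec_model

# A minimal group-based document: two enzymes declared as species inside the
# "Protein" group, concentrations in initialAmount (0.12 and 1.4 mmol/gDW),
# one of them consumed by R1 with stoichiometry 0.1 (kcat = 10/h).
GROUP_DOC = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      xmlns:groups="http://www.sbml.org/sbml/level3/version1/groups/version1"
      level="3" version="1" fbc:required="false" groups:required="false">
  <model id="group_doc" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_A" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="P00363" compartment="c" initialAmount="0.12" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="P08921" compartment="c" initialAmount="1.4" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb0" value="0" constant="true"/>
      <parameter id="ub1000" value="1000" constant="true"/>
      <parameter id="ub10" value="10" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="R_EX_A" reversible="false" fast="false" fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub10">
        <listOfProducts>
          <speciesReference species="M_A" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R_R1" reversible="false" fast="false" fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub1000">
        <listOfReactants>
          <speciesReference species="M_A" stoichiometry="1" constant="true"/>
          <speciesReference species="P00363" stoichiometry="0.1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="R_R1" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
    <groups:listOfGroups>
      <groups:group groups:kind="classification" groups:id="Protein">
        <groups:listOfMembers groups:id="all_proteins">
          <groups:member groups:idRef="P00363"/>
          <groups:member groups:idRef="P08921"/>
        </groups:listOfMembers>
      </groups:group>
    </groups:listOfGroups>
  </model>
</sbml>
"""

# Legacy dialect: enzyme encoded as species prot_P00363 (no group), the
# reversible reaction split into R1/R1_REV, and the enzyme supplied by a
# prot_..._exchange reaction whose upper bound (0.3) carries the
# concentration.
LEGACY_DOC = """<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core"
      xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"
      level="3" version="1" fbc:required="false">
  <model id="legacy_doc" fbc:strict="true">
    <listOfCompartments><compartment id="c" constant="true"/></listOfCompartments>
    <listOfSpecies>
      <species id="M_A" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="M_B" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="M_prot_P00363" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb0" value="0" constant="true"/>
      <parameter id="ub1000" value="1000" constant="true"/>
      <parameter id="ub10" value="10" constant="true"/>
      <parameter id="ub03" value="0.3" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="R_EX_A" reversible="false" fast="false" fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub10">
        <listOfProducts><speciesReference species="M_A" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="R_EX_B" reversible="false" fast="false" fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub1000">
        <listOfReactants><speciesReference species="M_B" stoichiometry="1" constant="true"/></listOfReactants>
      </reaction>
      <reaction id="R_R1" reversible="false" fast="false" fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub1000">
        <listOfReactants>
          <speciesReference species="M_A" stoichiometry="1" constant="true"/>
          <speciesReference species="M_prot_P00363" stoichiometry="0.1" constant="true"/>
        </listOfReactants>
        <listOfProducts><speciesReference species="M_B" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="R_R1_REV" reversible="false" fast="false" fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub1000">
        <listOfReactants>
          <speciesReference species="M_B" stoichiometry="1" constant="true"/>
          <speciesReference species="M_prot_P00363" stoichiometry="0.1" constant="true"/>
        </listOfReactants>
        <listOfProducts><speciesReference species="M_A" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
      <reaction id="R_prot_P00363_exchange" reversible="false" fast="false" fbc:lowerFluxBound="lb0" fbc:upperFluxBound="ub03">
        <listOfProducts><speciesReference species="M_prot_P00363" stoichiometry="1" constant="true"/></listOfProducts>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="R_EX_B" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
"""


@pytest.fixture
def toy():
    """Unconstrained toy model (plain-FBA optimum 20)."""
    return make_toy_ec_model()


@pytest.fixture
def toy_p1():
    """Toy model with P1 measured at 0.3 mmol/gDW (EC optimum 12)."""
    return make_toy_ec_model(p1_concentration=0.3)


@pytest.fixture
def group_doc_path(tmp_path):
    p = tmp_path / "group_doc.xml"
    p.write_text(GROUP_DOC)
    return p


@pytest.fixture
def legacy_doc_path(tmp_path):
    p = tmp_path / "legacy_doc.xml"
    p.write_text(LEGACY_DOC)
    return p
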
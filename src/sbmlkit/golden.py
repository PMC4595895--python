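"""Hand-written golden documents.

Each document is a small, human-auditable SBML Level 3 file exercising
one construct; the ``bad_``-prefixed ones are deliberately defective and
:data:`EXPECTED_ISSUES` lists the (ruleId, severity) pairs their
validation must produce, exactly.

``comp_two_level.flat.xml`` is the hand-verified flattening of
``comp_two_level.xml``: sub1 instantiates the mid-level definition (whose
own submodel sub2 instantiates the leaf definition), the parent parameter
``p`` replaces mid's ``q`` through a port, and every surviving submodel
identifier appears under the ``sub1__`` / ``sub1__sub2__`` prefixes.
"""

_CORE = 'xmlns="http://www.sbml.org/sbml/level3/version1/core"'
_MML = 'xmlns="http://www.w3.org/1998/Math/MathML"'

GOLDEN_DOCUMENTS: dict[str, str] = {}

GOLDEN_DOCUMENTS["minimal_core.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="empty_model"/>
</sbml>
"""

GOLDEN_DOCUMENTS["core_reactions.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="decay_chain" timeUnits="second" substanceUnits="mole" extentUnits="mole" volumeUnits="litre">
    <listOfUnitDefinitions>
      <unitDefinition id="per_second">
        <listOfUnits>
          <unit kind="second" exponent="-1" scale="0" multiplier="1"/>
        </listOfUnits>
      </unitDefinition>
    </listOfUnitDefinitions>
    <listOfCompartments>
      <compartment id="cell" size="1" constant="true" units="litre" spatialDimensions="3"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="A" compartment="cell" initialAmount="10" hasOnlySubstanceUnits="true" boundaryCondition="false" constant="false" substanceUnits="mole"/>
      <species id="B" compartment="cell" initialAmount="0" hasOnlySubstanceUnits="true" boundaryCondition="false" constant="false" substanceUnits="mole"/>
      <species id="C" compartment="cell" initialAmount="0" hasOnlySubstanceUnits="true" boundaryCondition="false" constant="false" substanceUnits="mole"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="k1" value="0.3" constant="true" units="per_second"/>
      <parameter id="k2" value="0.1" constant="true" units="per_second"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="J1" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="A" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="B" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <kineticLaw>
          <math {_MML}><apply><times/><ci>k1</ci><ci>A</ci></apply></math>
        </kineticLaw>
      </reaction>
      <reaction id="J2" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="B" stoichiometry="2" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="C" stoichiometry="1" constant="true"/>
        </listOfProducts>
        <kineticLaw>
          <math {_MML}><apply><times/><ci>k2</ci><apply><power/><ci>B</ci><cn type="integer">2</cn></apply></apply></math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["core_function_event.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="fn_event">
    <listOfFunctionDefinitions>
      <functionDefinition id="square">
        <math {_MML}><lambda><bvar><ci>a</ci></bvar><apply><power/><ci>a</ci><cn type="integer">2</cn></apply></lambda></math>
      </functionDefinition>
    </listOfFunctionDefinitions>
    <listOfParameters>
      <parameter id="x" value="3" constant="false"/>
      <parameter id="y" value="0" constant="false"/>
    </listOfParameters>
    <listOfRules>
      <assignmentRule variable="y">
        <math {_MML}><apply><ci>square</ci><ci>x</ci></apply></math>
      </assignmentRule>
    </listOfRules>
    <listOfEvents>
      <event id="bump" useValuesFromTriggerTime="true">
        <trigger initialValue="true" persistent="true">
          <math {_MML}><apply><geq/><csymbol encoding="text" definitionURL="http://www.sbml.org/sbml/symbols/time">t</csymbol><cn type="integer">5</cn></apply></math>
        </trigger>
        <listOfEventAssignments>
          <eventAssignment variable="x">
            <math {_MML}><cn type="integer">7</cn></math>
          </eventAssignment>
        </listOfEventAssignments>
      </event>
    </listOfEvents>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["annotations_notes.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="annotated" metaid="meta_model">
    <notes><body xmlns="http://www.w3.org/1999/xhtml"><p>A tiny annotated model.</p></body></notes>
    <annotation><custom xmlns="http://example.org/custom" weight="2"><inner>payload text</inner></custom></annotation>
    <listOfParameters>
      <parameter id="p1" value="1" constant="true" metaid="meta_p1" sboTerm="SBO:0000002"/>
    </listOfParameters>
  </model>
</sbml>
"""

_FBC = 'xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2"'
GOLDEN_DOCUMENTS["fbc_small.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} {_FBC} fbc:required="false" level="3" version="1">
  <model id="mini_net" fbc:strict="true">
    <listOfCompartments>
      <compartment id="cy" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="glc" compartment="cy" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="0" fbc:chemicalFormula="C6H12O6"/>
      <species id="pyr" compartment="cy" initialAmount="0" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false" fbc:charge="-1" fbc:chemicalFormula="C3H3O3"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="lb" value="-1000" constant="true"/>
      <parameter id="zero" value="0" constant="true"/>
      <parameter id="ub" value="1000" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="glyc" reversible="false" fast="false" fbc:lowerFluxBound="zero" fbc:upperFluxBound="ub">
        <fbc:geneProductAssociation>
          <fbc:or>
            <fbc:and>
              <fbc:geneProductRef fbc:geneProduct="gA"/>
              <fbc:geneProductRef fbc:geneProduct="gB"/>
            </fbc:and>
            <fbc:geneProductRef fbc:geneProduct="gC"/>
          </fbc:or>
        </fbc:geneProductAssociation>
        <listOfReactants>
          <speciesReference species="glc" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="pyr" stoichiometry="2" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="ex_pyr" reversible="true" fast="false" fbc:lowerFluxBound="lb" fbc:upperFluxBound="ub">
        <listOfReactants>
          <speciesReference species="pyr" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj1">
      <fbc:objective fbc:id="obj1" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="ex_pyr" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
    <fbc:listOfGeneProducts>
      <fbc:geneProduct fbc:id="gA" fbc:label="gene_A"/>
      <fbc:geneProduct fbc:id="gB" fbc:label="gene_B"/>
      <fbc:geneProduct fbc:id="gC" fbc:label="gene_C"/>
    </fbc:listOfGeneProducts>
  </model>
</sbml>
"""

_QUAL = 'xmlns:qual="http://www.sbml.org/sbml/level3/version1/qual/version1"'
GOLDEN_DOCUMENTS["qual_toggle.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} {_QUAL} qual:required="false" level="3" version="1">
  <model id="toggle">
    <listOfCompartments>
      <compartment id="nucleus" size="1" constant="true"/>
    </listOfCompartments>
    <qual:listOfQualitativeSpecies>
      <qual:qualitativeSpecies qual:id="A" qual:compartment="nucleus" qual:constant="false" qual:maxLevel="1" qual:initialLevel="1"/>
      <qual:qualitativeSpecies qual:id="B" qual:compartment="nucleus" qual:constant="false" qual:maxLevel="1" qual:initialLevel="0"/>
    </qual:listOfQualitativeSpecies>
    <qual:listOfTransitions>
      <qual:transition qual:id="tA">
        <qual:listOfInputs>
          <qual:input qual:qualitativeSpecies="B" qual:transitionEffect="none" qual:sign="negative"/>
        </qual:listOfInputs>
        <qual:listOfOutputs>
          <qual:output qual:qualitativeSpecies="A" qual:transitionEffect="assignmentLevel"/>
        </qual:listOfOutputs>
        <qual:listOfFunctionTerms>
          <qual:functionTerm qual:resultLevel="1">
            <math {_MML}><apply><lt/><ci>B</ci><cn type="integer">1</cn></apply></math>
          </qual:functionTerm>
          <qual:defaultTerm qual:resultLevel="0"/>
        </qual:listOfFunctionTerms>
      </qual:transition>
      <qual:transition qual:id="tB">
        <qual:listOfInputs>
          <qual:input qual:qualitativeSpecies="A" qual:transitionEffect="none" qual:sign="negative"/>
        </qual:listOfInputs>
        <qual:listOfOutputs>
          <qual:output qual:qualitativeSpecies="B" qual:transitionEffect="assignmentLevel"/>
        </qual:listOfOutputs>
        <qual:listOfFunctionTerms>
          <qual:functionTerm qual:resultLevel="1">
            <math {_MML}><apply><lt/><ci>A</ci><cn type="integer">1</cn></apply></math>
          </qual:functionTerm>
          <qual:defaultTerm qual:resultLevel="0"/>
        </qual:listOfFunctionTerms>
      </qual:transition>
    </qual:listOfTransitions>
  </model>
</sbml>
"""

_GROUPS = 'xmlns:groups="http://www.sbml.org/sbml/level3/version1/groups/version1"'
GOLDEN_DOCUMENTS["groups_simple.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} {_GROUPS} groups:required="false" level="3" version="1">
  <model id="grouped">
    <listOfCompartments>
      <compartment id="c1" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="S1" compartment="c1" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="S2" compartment="c1" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="R1" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="S1" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="S2" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
    </listOfReactions>
    <groups:listOfGroups>
      <groups:group groups:id="pathway" groups:kind="collection">
        <groups:listOfMembers>
          <groups:member groups:idRef="S1"/>
          <groups:member groups:idRef="R1"/>
          <groups:member groups:idRef="inner"/>
        </groups:listOfMembers>
      </groups:group>
      <groups:group groups:id="inner" groups:kind="classification">
        <groups:listOfMembers>
          <groups:member groups:idRef="S2"/>
        </groups:listOfMembers>
      </groups:group>
    </groups:listOfGroups>
  </model>
</sbml>
"""

_COMP = 'xmlns:comp="http://www.sbml.org/sbml/level3/version1/comp/version1"'
GOLDEN_DOCUMENTS["comp_two_level.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} {_COMP} comp:required="true" level="3" version="1">
  <model id="top">
    <listOfParameters>
      <parameter id="p" value="2.5" constant="true"/>
      <parameter id="wt" constant="false"/>
    </listOfParameters>
    <listOfRules>
      <assignmentRule variable="wt">
        <math {_MML}><apply><times/><ci>p</ci><cn type="integer">2</cn></apply></math>
      </assignmentRule>
    </listOfRules>
    <comp:listOfSubmodels>
      <comp:submodel comp:id="sub1" comp:modelRef="mid"/>
    </comp:listOfSubmodels>
  </model>
  <comp:listOfModelDefinitions>
    <comp:modelDefinition id="mid">
      <listOfParameters>
        <parameter id="q" value="0.5" constant="true"/>
        <parameter id="wm" constant="false"/>
      </listOfParameters>
      <listOfRules>
        <assignmentRule variable="wm">
          <math {_MML}><apply><plus/><ci>q</ci><cn type="integer">1</cn></apply></math>
        </assignmentRule>
      </listOfRules>
      <comp:listOfSubmodels>
        <comp:submodel comp:id="sub2" comp:modelRef="leaf"/>
      </comp:listOfSubmodels>
      <comp:listOfPorts>
        <comp:port comp:id="q_port" comp:idRef="q"/>
      </comp:listOfPorts>
    </comp:modelDefinition>
    <comp:modelDefinition id="leaf">
      <listOfParameters>
        <parameter id="kq" value="1.5" constant="true"/>
        <parameter id="wl" constant="false"/>
      </listOfParameters>
      <listOfRules>
        <assignmentRule variable="wl">
          <math {_MML}><apply><times/><ci>kq</ci><cn type="integer">3</cn></apply></math>
        </assignmentRule>
      </listOfRules>
    </comp:modelDefinition>
  </comp:listOfModelDefinitions>
</sbml>
"""
# the parent parameter p replaces mid's q (via the port), so the
# flattened sub1__wm rule must read "p + 1"
GOLDEN_DOCUMENTS["comp_two_level.xml"] = GOLDEN_DOCUMENTS[
    "comp_two_level.xml"].replace(
    '      <parameter id="p" value="2.5" constant="true"/>',
    '''      <parameter id="p" value="2.5" constant="true">
        <comp:listOfReplacedElements>
          <comp:replacedElement comp:submodelRef="sub1" comp:portRef="q_port"/>
        </comp:listOfReplacedElements>
      </parameter>''')

GOLDEN_DOCUMENTS["comp_two_level.flat.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml level="3" version="1" {_CORE}>
  <model id="top">
    <listOfParameters>
      <parameter id="p" constant="true" value="2.5"/>
      <parameter id="wt" constant="false"/>
      <parameter id="sub1__wm" constant="false"/>
      <parameter id="sub1__sub2__kq" constant="true" value="1.5"/>
      <parameter id="sub1__sub2__wl" constant="false"/>
    </listOfParameters>
    <listOfRules>
      <assignmentRule variable="wt">
        <math {_MML}><apply><times/><ci> p </ci><cn type="integer">2</cn></apply></math>
      </assignmentRule>
      <assignmentRule variable="sub1__wm">
        <math {_MML}><apply><plus/><ci> p </ci><cn type="integer">1</cn></apply></math>
      </assignmentRule>
      <assignmentRule variable="sub1__sub2__wl">
        <math {_MML}><apply><times/><ci> sub1__sub2__kq </ci><cn type="integer">3</cn></apply></math>
      </assignmentRule>
    </listOfRules>
  </model>
</sbml>
"""

_ARR = 'xmlns:arrays="http://www.sbml.org/sbml/level3/version1/arrays/version1"'
GOLDEN_DOCUMENTS["arrays_grid.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_ARR} {_CORE} arrays:required="true" level="3" version="1">
  <model id="grid">
    <listOfCompartments>
      <compartment id="c" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="s" compartment="c" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false">
        <arrays:listOfDimensions>
          <arrays:dimension arrays:id="i" arrays:arrayDimension="0" arrays:size="n"/>
          <arrays:dimension arrays:id="j" arrays:arrayDimension="1" arrays:size="m"/>
        </arrays:listOfDimensions>
      </species>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="n" value="2" constant="true"/>
      <parameter id="m" value="2" constant="true"/>
      <parameter id="kdeg" value="0.2" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="deg" reversible="false" fast="false">
        <arrays:listOfDimensions>
          <arrays:dimension arrays:id="i" arrays:arrayDimension="0" arrays:size="n"/>
          <arrays:dimension arrays:id="j" arrays:arrayDimension="1" arrays:size="m"/>
        </arrays:listOfDimensions>
        <listOfReactants>
          <speciesReference species="s" stoichiometry="1" constant="true">
            <arrays:listOfIndices>
              <arrays:index arrays:referencedAttribute="species" arrays:arrayDimension="0">
                <math {_MML}><ci>i</ci></math>
              </arrays:index>
              <arrays:index arrays:referencedAttribute="species" arrays:arrayDimension="1">
                <math {_MML}><ci>j</ci></math>
              </arrays:index>
            </arrays:listOfIndices>
          </speciesReference>
        </listOfReactants>
        <kineticLaw>
          <math {_MML}><apply><times/><ci>kdeg</ci><apply><selector/><ci>s</ci><ci>i</ci><ci>j</ci></apply></apply></math>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["unknown_package.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} xmlns:distrib="http://www.sbml.org/sbml/level3/version1/distrib/version1" distrib:required="false" level="3" version="1">
  <model id="with_unknown">
    <listOfParameters>
      <parameter id="mu" value="3.5" constant="true">
        <distrib:uncertainty><distrib:uncertParameter distrib:type="standardDeviation" distrib:value="0.25"/></distrib:uncertainty>
      </parameter>
    </listOfParameters>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["unknown_required_package.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} xmlns:dyn="http://www.sbml.org/sbml/level3/version1/dyn/version1" dyn:required="true" level="3" version="1">
  <model id="needs_dyn">
    <listOfParameters>
      <parameter id="a" value="1" constant="true"/>
    </listOfParameters>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["local_parameters.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="locals">
    <listOfCompartments>
      <compartment id="c" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="S" compartment="c" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="Ra" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="S" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <kineticLaw>
          <math {_MML}><apply><times/><ci>k</ci><ci>S</ci></apply></math>
          <listOfLocalParameters>
            <localParameter id="k" value="0.5"/>
          </listOfLocalParameters>
        </kineticLaw>
      </reaction>
      <reaction id="Rb" reversible="false" fast="false">
        <listOfReactants>
          <speciesReference species="S" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <kineticLaw>
          <math {_MML}><apply><times/><ci>k</ci><ci>S</ci></apply></math>
          <listOfLocalParameters>
            <localParameter id="k" value="0.9"/>
          </listOfLocalParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["units_catalog.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="units_model" timeUnits="second">
    <listOfUnitDefinitions>
      <unitDefinition id="mole_per_litre">
        <listOfUnits>
          <unit kind="mole" exponent="1" scale="0" multiplier="1"/>
          <unit kind="litre" exponent="-1" scale="0" multiplier="1"/>
        </listOfUnits>
      </unitDefinition>
      <unitDefinition id="umol">
        <listOfUnits>
          <unit kind="mole" exponent="1" scale="-6" multiplier="1"/>
        </listOfUnits>
      </unitDefinition>
      <unitDefinition id="newton_alias">
        <listOfUnits>
          <unit kind="newton" exponent="1" scale="0" multiplier="1"/>
        </listOfUnits>
      </unitDefinition>
    </listOfUnitDefinitions>
    <listOfParameters>
      <parameter id="conc" value="2" constant="true" units="mole_per_litre"/>
      <parameter id="force" value="1" constant="true" units="newton_alias"/>
    </listOfParameters>
  </model>
</sbml>
"""

# ---------------------------------------------------------------------
# deliberately defective documents
# ---------------------------------------------------------------------

GOLDEN_DOCUMENTS["bad_dup_sid.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="dup">
    <listOfCompartments>
      <compartment id="c" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="twin" compartment="c" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="twin" value="1" constant="true"/>
    </listOfParameters>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["bad_unit_mismatch.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} level="3" version="1">
  <model id="mismatch">
    <listOfParameters>
      <parameter id="len" value="1" constant="false" units="metre"/>
      <parameter id="dur" value="4" constant="true" units="second"/>
    </listOfParameters>
    <listOfRules>
      <assignmentRule variable="len">
        <math {_MML}><ci>dur</ci></math>
      </assignmentRule>
    </listOfRules>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["bad_fbc_bounds.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} {_FBC} fbc:required="false" level="3" version="1">
  <model id="bad_bounds" fbc:strict="true">
    <listOfCompartments>
      <compartment id="c" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="S" compartment="c" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="five" value="5" constant="true"/>
      <parameter id="one" value="1" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="Rx" reversible="false" fast="false" fbc:lowerFluxBound="five" fbc:upperFluxBound="one">
        <listOfReactants>
          <speciesReference species="S" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["bad_qual_level.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} {_QUAL} qual:required="false" level="3" version="1">
  <model id="bad_levels">
    <listOfCompartments>
      <compartment id="c" size="1" constant="true"/>
    </listOfCompartments>
    <qual:listOfQualitativeSpecies>
      <qual:qualitativeSpecies qual:id="Q" qual:compartment="c" qual:constant="false" qual:maxLevel="1" qual:initialLevel="2"/>
    </qual:listOfQualitativeSpecies>
  </model>
</sbml>
"""

GOLDEN_DOCUMENTS["bad_comp_port.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_CORE} {_COMP} comp:required="true" level="3" version="1">
  <model id="dangling">
    <listOfParameters>
      <parameter id="p" value="1" constant="true">
        <comp:listOfReplacedElements>
          <comp:replacedElement comp:submodelRef="s1" comp:portRef="no_such_port"/>
        </comp:listOfReplacedElements>
      </parameter>
    </listOfParameters>
    <comp:listOfSubmodels>
      <comp:submodel comp:id="s1" comp:modelRef="inner"/>
    </comp:listOfSubmodels>
  </model>
  <comp:listOfModelDefinitions>
    <comp:modelDefinition id="inner">
      <listOfParameters>
        <parameter id="q" value="1" constant="true"/>
      </listOfParameters>
    </comp:modelDefinition>
  </comp:listOfModelDefinitions>
</sbml>
"""

GOLDEN_DOCUMENTS["bad_arrays_bounds.xml"] = f"""<?xml version="1.0" encoding="UTF-8"?>
<sbml {_ARR} {_CORE} arrays:required="true" level="3" version="1">
  <model id="oob">
    <listOfCompartments>
      <compartment id="c" size="1" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="s" compartment="c" initialAmount="1" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false">
        <arrays:listOfDimensions>
          <arrays:dimension arrays:id="d0" arrays:arrayDimension="0" arrays:size="n"/>
        </arrays:listOfDimensions>
      </species>
    </listOfSpecies>
    <listOfParameters>
      <parameter id="n" value="3" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="r" reversible="false" fast="false">
        <arrays:listOfDimensions>
          <arrays:dimension arrays:id="d0" arrays:arrayDimension="0" arrays:size="n"/>
        </arrays:listOfDimensions>
        <listOfReactants>
          <speciesReference species="s" stoichiometry="1" constant="true">
            <arrays:listOfIndices>
              <arrays:index arrays:referencedAttribute="species" arrays:arrayDimension="0">
                <math {_MML}><apply><plus/><ci>d0</ci><cn type="integer">1</cn></apply></math>
              </arrays:index>
            </arrays:listOfIndices>
          </speciesReference>
        </listOfReactants>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
"""

#: expected (ruleId, severity) lists for the defective documents, in the
#: deterministic order the validator reports them
EXPECTED_ISSUES: dict[str, list[tuple[str, str]]] = {
    "bad_dup_sid.xml": [("CORE-10301", "error")],
    "bad_unit_mismatch.xml": [("CORE-10511", "warning")],
    "bad_fbc_bounds.xml": [("FBC-20707", "error")],
    "bad_qual_level.xml": [("QUAL-20301", "error")],
    "bad_comp_port.xml": [("COMP-20907", "error")],
    "bad_arrays_bounds.xml": [("ARR-31014", "error")],
    "unknown_required_package.xml": [("CORE-99107", "error")],
}
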
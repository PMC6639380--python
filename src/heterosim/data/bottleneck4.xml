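<?xml version="1.0" encoding="UTF-8"?>
<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" xmlns:fbc="http://www.sbml.org/sbml/level3/version1/fbc/version2" sboTerm="SBO:0000624" level="3" version="1" fbc:required="false">
  <model metaid="meta_toy_bottleneck_pair" id="toy_bottleneck_pair" fbc:strict="true">
    <listOfUnitDefinitions>
      <unitDefinition id="mmol_per_gDW_per_hr">
        <listOfUnits>
          <unit kind="mole" exponent="1" scale="-3" multiplier="1"/>
          <unit kind="gram" exponent="-1" scale="0" multiplier="1"/>
          <unit kind="second" exponent="-1" scale="0" multiplier="3600"/>
        </listOfUnits>
      </unitDefinition>
    </listOfUnitDefinitions>
    <listOfCompartments>
      <compartment id="c" constant="true"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="M_M1" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="M_M2" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="M_M3" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="M_M4" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
      <species id="M_M5" compartment="c" hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false"/>
    </listOfSpecies>
    <listOfParameters>
      <parameter sboTerm="SBO:0000626" id="cobra_default_lb" value="-1000" constant="true"/>
      <parameter sboTerm="SBO:0000626" id="cobra_default_ub" value="1000" constant="true"/>
      <parameter sboTerm="SBO:0000626" id="cobra_0_bound" value="0" constant="true"/>
      <parameter sboTerm="SBO:0000626" id="minus_inf" value="-INF" constant="true"/>
      <parameter sboTerm="SBO:0000626" id="plus_inf" value="INF" constant="true"/>
      <parameter sboTerm="SBO:0000625" id="R_EX_M1_upper_bound" value="10" units="mmol_per_gDW_per_hr" constant="true"/>
      <parameter sboTerm="SBO:0000625" id="R_R1_upper_bound" value="10" units="mmol_per_gDW_per_hr" constant="true"/>
      <parameter sboTerm="SBO:0000625" id="R_R2_upper_bound" value="10" units="mmol_per_gDW_per_hr" constant="true"/>
      <parameter sboTerm="SBO:0000625" id="R_R3_upper_bound" value="10" units="mmol_per_gDW_per_hr" constant="true"/>
      <parameter sboTerm="SBO:0000625" id="R_R4_upper_bound" value="10" units="mmol_per_gDW_per_hr" constant="true"/>
      <parameter sboTerm="SBO:0000625" id="R_BIO_upper_bound" value="1000000" units="mmol_per_gDW_per_hr" constant="true"/>
    </listOfParameters>
    <listOfReactions>
      <reaction id="R_EX_M1" reversible="false" fast="false" fbc:lowerFluxBound="cobra_0_bound" fbc:upperFluxBound="R_EX_M1_upper_bound">
        <listOfProducts>
          <speciesReference species="M_M1" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R_R1" reversible="false" fast="false" fbc:lowerFluxBound="cobra_0_bound" fbc:upperFluxBound="R_R1_upper_bound">
        <listOfReactants>
          <speciesReference species="M_M1" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_M2" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R_R2" reversible="false" fast="false" fbc:lowerFluxBound="cobra_0_bound" fbc:upperFluxBound="R_R2_upper_bound">
        <listOfReactants>
          <speciesReference species="M_M2" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_M3" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R_R3" reversible="false" fast="false" fbc:lowerFluxBound="cobra_0_bound" fbc:upperFluxBound="R_R3_upper_bound">
        <listOfReactants>
          <speciesReference species="M_M3" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_M4" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R_R4" reversible="false" fast="false" fbc:lowerFluxBound="cobra_0_bound" fbc:upperFluxBound="R_R4_upper_bound">
        <listOfReactants>
          <speciesReference species="M_M4" stoichiometry="1" constant="true"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="M_M5" stoichiometry="1" constant="true"/>
        </listOfProducts>
      </reaction>
      <reaction id="R_BIO" reversible="false" fast="false" fbc:lowerFluxBound="cobra_0_bound" fbc:upperFluxBound="R_BIO_upper_bound">
        <listOfReactants>
          <speciesReference species="M_M5" stoichiometry="1" constant="true"/>
        </listOfReactants>
      </reaction>
    </listOfReactions>
    <fbc:listOfObjectives fbc:activeObjective="obj">
      <fbc:objective fbc:id="obj" fbc:type="maximize">
        <fbc:listOfFluxObjectives>
          <fbc:fluxObjective fbc:reaction="R_BIO" fbc:coefficient="1"/>
        </fbc:listOfFluxObjectives>
      </fbc:objective>
    </fbc:listOfObjectives>
  </model>
</sbml>
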
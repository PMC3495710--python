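<?xml version="1.0" encoding="UTF-8"?>
<!-- Hand-written restricted-SBML encoding of the enzymatic reaction model
     E + S <-> ES -> E + P (amounts, single compartment, irreversible
     mass-action kinetic laws). -->
<sbml xmlns="http://www.sbml.org/sbml/level2/version4" level="2" version="4">
  <model id="enzymatic">
    <listOfCompartments>
      <compartment id="cell" size="1"/>
    </listOfCompartments>
    <listOfSpecies>
      <species id="S" compartment="cell" initialAmount="12"/>
      <species id="E" compartment="cell" initialAmount="10"/>
      <species id="ES" compartment="cell" initialAmount="0"/>
      <species id="P" compartment="cell" initialAmount="0"/>
    </listOfSpecies>
    <listOfReactions>
      <reaction id="r1" reversible="false">
        <listOfReactants>
          <speciesReference species="E"/>
          <speciesReference species="S"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="ES"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <times/>
              <ci> k1 </ci>
              <ci> E </ci>
              <ci> S </ci>
            </apply>
          </math>
          <listOfParameters>
            <parameter id="k1" value="0.184"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="r2" reversible="false">
        <listOfReactants>
          <speciesReference species="ES"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="E"/>
          <speciesReference species="S"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <times/>
              <ci> k2 </ci>
              <ci> ES </ci>
            </apply>
          </math>
          <listOfParameters>
            <parameter id="k2" value="0.016"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
      <reaction id="r3" reversible="false">
        <listOfReactants>
          <speciesReference species="ES"/>
        </listOfReactants>
        <listOfProducts>
          <speciesReference species="E"/>
          <speciesReference species="P"/>
        </listOfProducts>
        <kineticLaw>
          <math xmlns="http://www.w3.org/1998/Math/MathML">
            <apply>
              <times/>
              <ci> k3 </ci>
              <ci> ES </ci>
            </apply>
          </math>
          <listOfParameters>
            <parameter id="k3" value="0.211"/>
          </listOfParameters>
        </kineticLaw>
      </reaction>
    </listOfReactions>
  </model>
</sbml>
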
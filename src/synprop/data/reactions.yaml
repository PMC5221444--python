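# The five anaerobic reactions governing syntrophic propionate degradation.
# Coefficients are signed (negative = consumed) exact rationals; dg0_prime is
# the standard-condition free energy (pH 7 prime convention) in kJ per
# reaction as written, from the standard compilation of Thauer et al.
reactions:
  - name: propionate_oxidation
    dg0_prime: 76.1
    stoichiometry:
      propionate: -1
      H2O: -3
      acetate: 1
      HCO3-: 1
      H+: 1
      H2: 3
  - name: hydrogenotrophic_methanogenesis
    dg0_prime: -135.6
    stoichiometry:
      H2: -4
      HCO3-: -1
      H+: -1
      CH4: 1
      H2O: 3
  - name: acetoclastic_methanogenesis
    dg0_prime: -31.0
    stoichiometry:
      acetate: -1
      H2O: -1
      CH4: 1
      HCO3-: 1
  - name: syntrophic_acetate_oxidation
    dg0_prime: 104.6
    stoichiometry:
      acetate: -1
      H2O: -4
      HCO3-: 2
      H2: 4
      H+: 1
  - name: autotrophic_homoacetogenesis
    dg0_prime: -104.6
    stoichiometry:
      acetate: 1
      H2O: 4
      HCO3-: -2
      H2: -4
      H+: -1
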
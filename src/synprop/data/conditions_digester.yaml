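# Mesophilic digester reference conditions: 37 degC, 1 mmol/L acetate and
# propionate, 20 mmol/L bicarbonate, 0.6 atm methane, pH 7.  Hydrogen partial
# pressure is left unset; sweeps and crossover solvers supply it.
temperature: 310.15
pH: 7.0
activities:
  acetate: 1.0e-3
  propionate: 1.0e-3
  HCO3-: 2.0e-2
  CH4: 0.6
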
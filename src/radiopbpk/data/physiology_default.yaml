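# Reference adult physiology: organ masses [g] and fractions of cardiac
# output [%]; cardiac output allometric in L/(h·kg^exponent).
organ_masses:
  lungs: 1000
  kidney: 299
  liver: 1910
  brain: 1420
  venous_blood: 2350
  rest_of_body: 64371
  arterial_blood: 2350
flow_fractions:
  kidney: 22
  liver: 17.5
  brain: 11.4
  rest_of_body: 49.1
tissue_density: 1.0
cardiac_output_coeff: 15
cardiac_output_exponent: 0.74
body_weight: 70
brain_cbv_fraction: 0.038
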
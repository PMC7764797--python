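schema: pbpkddi-drug/1
name: caffeine
notes: >
  Illustrative parameterization: dominant linear CYP1A2 metabolism with a
  small unspecific route; dietary flag enables background-intake
  (non-compliance) scenarios. PK parameter values are literature-plausible
  placeholders.
molecular_weight: 194.19 g/mol
fu: 0.7
blood_plasma_ratio: 1.0
kp:
  default: 0.8
pathways:
  - enzyme: CYP1A2
    kinetics: linear
    cl_int: 0.0914 L/min/umol
  - enzyme: UNSPECIFIC
    kinetics: unspecific_hepatic
    cl_apparent: 0.0077 L/min
dietary: true
absorption:
  oral:
    ka: 0.06 1/min
    f_abs: 1.0
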
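schema: pbpkddi-drug/1
name: tizanidine
notes: >
  Illustrative parameterization: linear CYP1A2 metabolism as the only
  clearance pathway (pure CYP1A2 victim). PK parameter values are
  literature-plausible placeholders.
molecular_weight: 253.71 g/mol
fu: 0.7
blood_plasma_ratio: 1.0
kp:
  default: 2.0
pathways:
  - enzyme: CYP1A2
    kinetics: linear
    cl_int: 3.13 L/min/umol
absorption:
  oral:
    ka: 0.03 1/min
    f_abs: 0.95
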
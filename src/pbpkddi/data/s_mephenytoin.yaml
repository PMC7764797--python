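schema: pbpkddi-drug/1
name: s_mephenytoin
notes: >
  Illustrative parameterization: linear CYP2C19 metabolism plus an unspecific
  hepatic clearance scaled from an apparent in vivo clearance (the unspecific
  route is insensitive to inhibitors). PK parameter values are
  literature-plausible placeholders.
molecular_weight: 218.25 g/mol
fu: 0.55
blood_plasma_ratio: 1.0
kp:
  default: 1.0
pathways:
  - enzyme: CYP2C19
    kinetics: linear
    cl_int: 0.24 L/min/umol
  - enzyme: UNSPECIFIC
    kinetics: unspecific_hepatic
    cl_apparent: 0.054 L/min
absorption:
  oral:
    ka: 0.025 1/min
    f_abs: 0.9
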
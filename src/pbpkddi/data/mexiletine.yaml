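schema: pbpkddi-drug/1
name: mexiletine
notes: >
  Illustrative parameterization: three parallel linear routes via CYP2D6,
  CYP1A2 and an unspecific clearance; moderate CYP1A2 inhibitor. PK
  parameter values are literature-plausible placeholders.
molecular_weight: 179.26 g/mol
fu: 0.3
blood_plasma_ratio: 1.1
kp:
  default: 6.0
pathways:
  - enzyme: CYP2D6
    kinetics: linear
    cl_int: 4.31 L/min/umol
  - enzyme: CYP1A2
    kinetics: linear
    cl_int: 0.57 L/min/umol
  - enzyme: UNSPECIFIC
    kinetics: unspecific_hepatic
    cl_apparent: 0.6 L/min
inhibitions:
  - target_enzyme: CYP1A2
    mechanism: competitive
    ki: 0.28 uM
    basis: in_vitro
absorption:
  oral:
    ka: 0.02 1/min
    f_abs: 0.9
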
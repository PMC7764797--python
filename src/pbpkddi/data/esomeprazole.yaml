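schema: pbpkddi-drug/1
name: esomeprazole
notes: >
  Illustrative parameterization of the S-enantiomer of omeprazole: parallel
  linear CYP2C19 and CYP3A4 pathways with CYP2C19 autoinhibition by
  time-dependent inactivation. Racemic omeprazole is modeled as esomeprazole
  plus r_omeprazole co-dosed at half the racemate dose each. PK parameter
  values are literature-plausible placeholders.
molecular_weight: 345.42 g/mol
fu: 0.05
blood_plasma_ratio: 0.6
kp:
  default: 0.4
pathways:
  - enzyme: CYP2C19
    kinetics: linear
    cl_int: 16.2 L/min/umol
  - enzyme: CYP3A4
    kinetics: linear
    cl_int: 1.21 L/min/umol
inhibitions:
  - target_enzyme: CYP2C19
    mechanism: competitive
    ki: 3.1 uM
    basis: in_vitro
  - target_enzyme: CYP2C19
    mechanism: tdi
    k_i_tdi: 0.3 uM
    k_inact: 0.05 1/min
    basis: in_vitro
    metadata:
      k_inact_illustrative: true
absorption:
  oral:
    ka: 0.03 1/min
    f_abs: 0.9
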
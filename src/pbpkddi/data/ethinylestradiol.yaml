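schema: pbpkddi-drug/1
name: ethinylestradiol
notes: >
  Illustrative parameterization: five parallel metabolic pathways (linear
  CYP3A4, CYP1A2, CYP2C9, CYP2C19 and saturable UGT1A1 glucuronidation);
  moderate CYP1A2 inhibitor with an optional time-dependent inactivation
  component (k_inact of 100 and 200 1/min are the two tested hypotheses).
  PK parameter values are literature-plausible placeholders.
molecular_weight: 296.40 g/mol
fu: 0.02
blood_plasma_ratio: 1.0
kp:
  default: 8.0
pathways:
  - enzyme: CYP3A4
    kinetics: linear
    cl_int: 3.15 L/min/umol
  - enzyme: CYP1A2
    kinetics: linear
    cl_int: 1.75 L/min/umol
  - enzyme: CYP2C9
    kinetics: linear
    cl_int: 1.31 L/min/umol
  - enzyme: CYP2C19
    kinetics: linear
    cl_int: 3.11 L/min/umol
  - enzyme: UGT1A1
    kinetics: saturable
    vmax: 2.24 umol/min/umol
    km: 1.0 uM
inhibitions:
  - target_enzyme: CYP1A2
    mechanism: competitive
    ki: 0.48 uM
    basis: optimized
    metadata:
      literature_uM: 10.6
  - target_enzyme: CYP1A2
    mechanism: tdi
    k_i_tdi: 0.48 uM
    k_inact: 100 1/min
    basis: optimized
    metadata:
      k_i_tdi_illustrative: true
      k_inact_tested_1_min: [100, 200]
absorption:
  oral:
    ka: 0.02 1/min
    f_abs: 0.6
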
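schema: pbpkddi-drug/1
name: moclobemide
notes: >
  Illustrative parameterization: saturable CYP2C19 metabolism plus an
  unspecific route, with CYP2C19 autoinhibition by time-dependent
  inactivation driving multiple-dose accumulation beyond linear
  superposition. PK parameter values are literature-plausible placeholders.
molecular_weight: 268.74 g/mol
fu: 0.5
blood_plasma_ratio: 0.8
kp:
  default: 1.2
pathways:
  - enzyme: CYP2C19
    kinetics: saturable
    vmax: 6.7 umol/min/umol
    km: 5.0 uM
  - enzyme: UNSPECIFIC
    kinetics: unspecific_hepatic
    cl_apparent: 0.4 L/min
inhibitions:
  - target_enzyme: CYP2C19
    mechanism: competitive
    ki: 203.83 uM
    basis: in_vitro
  - target_enzyme: CYP2C19
    mechanism: tdi
    k_i_tdi: 94.85 uM
    k_inact: 0.05 1/min
    basis: in_vitro
    metadata:
      k_inact_illustrative: true
absorption:
  oral:
    ka: 0.03 1/min
    f_abs: 0.95
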
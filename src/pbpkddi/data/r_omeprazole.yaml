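schema: pbpkddi-drug/1
name: r_omeprazole
notes: >
  Illustrative parameterization of the R-enantiomer of omeprazole: CYP2C19 is
  the dominant linear pathway (hence the sensitivity of its oral
  bioavailability to gut-wall CYP2C19 expression), with a minor CYP3A4 route
  and CYP2C19 autoinhibition by time-dependent inactivation. PK parameter
  values are literature-plausible placeholders.
molecular_weight: 345.42 g/mol
fu: 0.05
blood_plasma_ratio: 0.6
kp:
  default: 0.4
pathways:
  - enzyme: CYP2C19
    kinetics: linear
    cl_int: 8.0 L/min/umol
  - enzyme: CYP3A4
    kinetics: linear
    cl_int: 0.2 L/min/umol
inhibitions:
  - target_enzyme: CYP2C19
    mechanism: competitive
    ki: 5.3 uM
    basis: in_vitro
  - target_enzyme: CYP2C19
    mechanism: tdi
    k_i_tdi: 1.6 uM
    k_inact: 0.05 1/min
    basis: in_vitro
    metadata:
      k_inact_illustrative: true
absorption:
  oral:
    ka: 0.03 1/min
    f_abs: 0.9
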
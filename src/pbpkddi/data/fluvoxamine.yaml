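schema: pbpkddi-drug/1
name: fluvoxamine
notes: >
  Illustrative parameterization: pathway structure (saturable CYP2D6 plus
  linear CYP1A2) and interaction constants follow the network description;
  clearance, Km/Vmax, fu and Kp values are literature-plausible placeholders,
  not fitted values.
molecular_weight: 318.33 g/mol
fu: 0.23
blood_plasma_ratio: 1.0
kp:
  default: 5.0
pathways:
  - enzyme: CYP2D6
    kinetics: saturable
    vmax: 1.54 umol/min/umol
    km: 0.2 uM
  - enzyme: CYP1A2
    kinetics: linear
    cl_int: 0.44 L/min/umol
inhibitions:
  - target_enzyme: CYP1A2
    mechanism: competitive
    ki: 2.97 nM
    basis: in_vivo_unbound
  - target_enzyme: CYP2C19
    mechanism: competitive
    ki: 3.6 nM
    basis: in_vivo_unbound
absorption:
  oral:
    ka: 0.02 1/min
    f_abs: 0.95
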
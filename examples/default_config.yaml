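# Full default parameter set of the model: value, units and provenance
# per symbol. Load with pyrdyn.load_parameters() or pass to any
# `pyrdyn` CLI command; override any subset, e.g. the oscillation-regime
# constants k2/k3/k9/h_UMP1/r. Optional per-command sections:
#   simulate: {t_end, report_step}   scan: {hill_step, r_values, t_end}
parameters:
  k1:
    value: 0.012
    units: mM/s
    provenance: literature
  k2:
    value: 0.31
    units: mM/s
    provenance: literature
  k3:
    value: 0.351
    units: mM/s
    provenance: literature
  k4f:
    value: 1.27
    units: mM/s
    provenance: literature
  k4r:
    value: 0.225
    units: mM/s
    provenance: literature
  k4:
    value: 12.28
    units: '1'
    provenance: literature
  k5:
    value: 3.9
    units: mM/s
    provenance: literature
  k5prpp:
    value: 7.5
    units: '1'
    provenance: literature
  k6:
    value: 0.73
    units: mM/s
    provenance: literature
  k7:
    value: 0.393
    units: mM/s
    provenance: literature
  k8:
    value: 0.11
    units: mM/s
    provenance: literature
  k9:
    value: 1.74e-05
    units: mM/s
    provenance: literature
  k10:
    value: 0.002
    units: 1/s
    provenance: default
  k11:
    value: 0.001
    units: 1/s
    provenance: default
  k22:
    value: 0.0001
    units: 1/s
    provenance: default
  k23:
    value: 0.0001
    units: 1/s
    provenance: default
  K_UMP1:
    value: 0.05
    units: mM
    provenance: default
  h_UMP1:
    value: 1.4
    units: '1'
    provenance: default
  K_UDP1:
    value: 2.0
    units: mM
    provenance: default
  h_UDP1:
    value: 1.0
    units: '1'
    provenance: default
  K_UTP1:
    value: 0.3
    units: mM
    provenance: default
  h_UTP1:
    value: 1.0
    units: '1'
    provenance: default
  K_IMP1:
    value: 1.0
    units: mM
    provenance: default
  Ka_IMP1:
    value: 1.0
    units: mM
    provenance: default
  d_IMP:
    value: 1.0
    units: '1'
    provenance: default
  Km_CAP2:
    value: 0.5
    units: mM
    provenance: default
  h_CAP:
    value: 1.0
    units: '1'
    provenance: default
  K_CTP2:
    value: 0.5
    units: mM
    provenance: default
  K_ATP2:
    value: 2.0
    units: mM
    provenance: default
  K_UTP2:
    value: 1.0
    units: mM
    provenance: default
  d_CTP2:
    value: 0.1
    units: '1'
    provenance: default
  d_ATP2:
    value: 2.0
    units: '1'
    provenance: default
  d_UTP2:
    value: 0.3
    units: '1'
    provenance: default
  w2:
    value: 1.0
    units: '1'
    provenance: default
  Km_CAASP3:
    value: 1.0
    units: mM
    provenance: default
  Km_DHO4:
    value: 0.5
    units: mM
    provenance: default
  Km_ORO4:
    value: 0.5
    units: mM
    provenance: default
  Ki_ORO4:
    value: 0.5
    units: mM
    provenance: default
  Km_ORO5:
    value: 0.5
    units: mM
    provenance: default
  Km_OMP6:
    value: 0.2
    units: mM
    provenance: default
  Km_UMP7:
    value: 0.05
    units: mM
    provenance: default
  K_UTP71:
    value: 0.2
    units: mM
    provenance: default
  K_UTP72:
    value: 1.0
    units: mM
    provenance: default
  h_UTP7:
    value: 4.0
    units: '1'
    provenance: default
  r:
    value: 1.0
    units: '1'
    provenance: default
  Km_UDP8:
    value: 0.3
    units: mM
    provenance: default
  Km_UTP9:
    value: 1.0
    units: mM
    provenance: default
  K_CTP9:
    value: 0.3
    units: mM
    provenance: default
  h_UTP9:
    value: 2.0
    units: '1'
    provenance: default
external:
  atp: 9.6
  imp: 0.27
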
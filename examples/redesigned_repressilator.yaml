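schema: 1
model: tomazou
nodes:
- N1
- N2
- N3
- N4
edges:
- N2 |- N1
- N3 |- N2
- N1 |- N3
- N4 |- N3
- N2 <- Y
- N4 <- U
proteases:
- name: C
  targets:
  - N1
  - N2
  - N3
  kcat: 1.2
  Km: 40.0
  conc: 50.0
- name: L
  targets:
  - N4
  kcat: 1.2
  Km: 40.0
  conc: 50.0
inducers:
- name: I2
  edge: N2 <- Y
  K: 10.0
  conc: 10.0
- name: I1
  edge: N4 <- U
  K: 10.0
  conc: 10.0
parameters:
  Y: 100.0
  U: 100.0
initial_conditions:
  P@N1: 100.0
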
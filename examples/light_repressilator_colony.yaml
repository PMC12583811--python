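schema: 1
model: elowitz
nodes:
- N1
- N2
- N3
edges:
- N2 |- N1
- N3 |- N2
- N1 |- N3
- N1 <- LIGHT
parameters:
  LIGHT: 60.0
initial_conditions:
  P@N1: 100.0
rules:
- symbol: LIGHT
  waveform: sine
  period: 432.0
  mean: 60.0
  amplitude: 45.0
  phase: 0.0
spatial:
  nx: 224
  ny: 224
  h: 1.0
  D_c: 0.01
  k: 0.1
  c_star: 0.99
  t_end: 1650.0
  dt: 0.25
  snapshot_every: 550.0
  burn_in: 6480.0
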
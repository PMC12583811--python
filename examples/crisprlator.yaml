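schema: 1
model: crispri
nodes:
- N1
- N2
- N3
edges:
- N1:CRISPRI |- N3
- N2:CRISPRI |- N1
- N3:CRISPRI |- N2
initial_conditions:
  P@N1: 50.0
  sgRNA@N1: 10.0
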
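schema: 1
model: elowitz
nodes:
- N1
- N2
- N3
edges:
- N1 <- R1
- N2 |- N1
- N3 |- N1
- N3 |- N2
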
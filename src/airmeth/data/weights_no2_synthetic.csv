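cpg_id,weight,gene
cg70000001,0.002,SYN_N1
cg70000002,-0.001,SYN_N2
cg70000003,0.001,SYN_N3
cg70000004,0.001,SYN_N4
cg70000005,-0.002,SYN_N5
cg70000006,0.001,SYN_N6
cg70000007,0.002,SYN_N7
cg70000008,-0.001,SYN_N8
cg70000009,0.001,SYN_N9
cg70000010,0.001,SYN_N10
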
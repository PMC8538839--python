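cpg_id,weight,gene
cg80000001,0.001,SYN_A1
cg80000002,-0.002,SYN_A2
cg80000003,0.001,SYN_A3
cg80000004,0.002,SYN_A4
cg80000005,-0.001,SYN_A5
cg80000006,0.001,SYN_A6
cg80000007,0.003,SYN_A7
cg80000008,-0.001,SYN_A8
cg80000009,0.001,SYN_A9
cg80000010,0.002,SYN_A10
cg80000011,-0.002,SYN_A11
cg80000012,0.001,SYN_A12
cg80000013,0.001,SYN_A13
cg80000014,-0.001,SYN_A14
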
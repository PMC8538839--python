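cpg_id,weight,gene
cg00905156,0.001,FAM13A
cg06849931,-0.001,NOTCH4
cg15082635,0.001,GNB2L1;SNORD96A
cg18640183,0.001,P4HA2
cg20340716,-0.002,USP43
cg24127244,0.001,SRPRB
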
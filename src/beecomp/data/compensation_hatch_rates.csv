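group,L_target,h
control,300,56
1,300,88
10,300,98
100,300,107
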
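stage,T1-2,T3,T4
T1-2,19,25,11
T3,17,18,21
T4,5,15,15
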
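stage,T1-2,T3,T4
T1-2,14,18,9
T3,12,11,11
T4,10,8,5
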
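stage,men,women
T1-2,27,14
T3,34,24
T4,27,20
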
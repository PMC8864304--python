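stratum,deaths
HQVR,119802
LMM,84414
HMM,1221418
passthrough,54593
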
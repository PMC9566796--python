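,T1,T2,T3
T1,1,2,1/3
T2,1/2,1,1/5
T3,3,5,1
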
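,S1,S2,S3,S4
S1,1,1/2,1/3,1/7
S2,2,1,1/5,1/6
S3,3,5,1,1/4
S4,7,6,4,1
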
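,O1,O2,O3,O4
O1,1,2,1/2,4
O2,1/2,1,1/3,3
O3,2,3,1,5
O4,1/4,1/3,1/5,1
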
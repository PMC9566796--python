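,W1,W2,W3
W1,1,1/7,1/2
W2,7,1,4
W3,2,1/4,1
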
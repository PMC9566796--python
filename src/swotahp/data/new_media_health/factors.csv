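id,group,intensity,description
S1,S,1,Health content reaches the public free of time and space constraints
S2,S,2,Varied and accessible content presentation formats
S3,S,4,Flexible audience roles in the health-communication chain
S4,S,6,Accurate user profiling through recommendation algorithms
W1,W,-2,No pre-qualification or content-evaluation system for creators
W2,W,-5,Uneven media literacy across audience age groups
W3,W,-1,Weak personal-information protection and spam
O1,O,4,National policies supporting internet health initiatives
O2,O,3,Active academic discussion of sport-medicine-media integration
O3,O,6,Pandemic-era surge in health aspirations and new-media use
O4,O,2,Rapid growth of online platforms and user bases
T1,T,-3,Malicious health marketing from commercial capital
T2,T,-2,Uneven regional development widening the health-perception divide
T3,T,-6,Audiences treating media content as a substitute for hospitals
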
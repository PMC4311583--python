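variable,component,plus_value,minus_value
A,CMC,1.0,0.1
B,Sucrose,0.2,0.02
C,YeastExtract,0.2,0.02
D,Peptone,0.5,0.05
E,K2HPO4,0.1,0.01
F,MgSO4,0.1,0.01
G,Temperature,37,28
H,pH,5,9
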
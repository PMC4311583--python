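run,CMC,Sucrose,YeastExtract,Peptone,K2HPO4,MgSO4,Temperature,pH,D1,D2,D3
1,1,1,-1,1,1,1,-1,-1,-1,1,-1
2,-1,1,1,-1,1,1,1,-1,-1,-1,1
3,1,-1,1,1,-1,1,1,1,-1,-1,-1
4,-1,1,-1,1,1,-1,1,1,1,-1,-1
5,-1,-1,1,-1,1,1,-1,1,1,1,-1
6,-1,-1,-1,1,-1,1,1,-1,1,1,1
7,1,-1,-1,-1,1,-1,1,1,-1,1,1
8,1,1,-1,-1,-1,1,-1,1,1,-1,1
9,1,1,1,-1,-1,-1,1,-1,1,1,-1
10,-1,1,1,1,-1,-1,-1,1,-1,1,1
11,1,-1,1,1,1,-1,-1,-1,1,-1,1
12,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1,-1
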
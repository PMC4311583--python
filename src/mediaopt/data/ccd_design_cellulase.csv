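run,CMC,MgSO4,pH
1,-1,-1,-1
2,1,-1,-1
3,-1,1,-1
4,1,1,-1
5,-1,-1,1
6,1,-1,1
7,-1,1,1
8,1,1,1
9,-1.681793,0,0
10,1.681793,0,0
11,0,-1.681793,0
12,0,1.681793,0
13,0,0,-1.681793
14,0,0,1.681793
15,0,0,0
16,0,0,0
17,0,0,0
18,0,0,0
19,0,0,0
20,0,0,0
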
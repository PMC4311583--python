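run,CMC,MgSO4,pH
1,0.5,0.05,7
2,1.5,0.05,7
3,0.5,0.5,7
4,1.5,0.5,7
5,0.5,0.05,10
6,1.5,0.05,10
7,0.5,0.5,10
8,1.5,0.5,10
9,0.159104,0.275,8.5
10,1.840896,0.275,8.5
11,1,-0.1034,8.5
12,1,0.653403,8.5
13,1,0.275,5.977311
14,1,0.275,11.02269
15,1,0.275,8.5
16,1,0.275,8.5
17,1,0.275,8.5
18,1,0.275,8.5
19,1,0.275,8.5
20,1,0.275,8.5
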
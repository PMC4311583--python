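run,response
1,23.6
2,24.55
3,25.05
4,24.85
5,16.85
6,24
7,20.55
8,22
9,25.1
10,29.95
11,20.7
12,25.7
13,29.8
14,20.05
15,24.3
16,29
17,28.7
18,24.75
19,26.9
20,29.8
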
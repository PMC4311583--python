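run,response
1,30.54
2,1.53
3,46.65
4,4.02
5,37.41
6,5.23
7,25.21
8,45.62
9,1.23
10,1.65
11,14.78
12,9.25
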
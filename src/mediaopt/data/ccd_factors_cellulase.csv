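name,center,step
CMC,1.0,0.5
MgSO4,0.275,0.225
pH,8.5,1.5
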
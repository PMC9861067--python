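object,standard_hr_hz,vmd_hz,ssa_vmd_hz
A,1.400,1.357,1.357
B,1.250,1.513,1.217
C,1.150,1.232,1.186
D,1.133,1.061,1.061
E,1.383,1.498,1.342
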
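object,standard_hr_hz,vmd_hz,ssa_vmd_hz
F,1.367,1.310,1.310
G,1.500,1.560,1.560
H,1.050,1.232,1.030
I,1.400,1.435,1.435
J,1.517,1.482,1.482
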
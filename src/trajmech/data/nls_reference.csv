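variant,sasa_r31,sasa_r32,sasa_r33,sphere_volume,translocation_retained
WT,187.72,122.09,81.35,2628.83,1
K17I,175.36,126.76,87.48,2502.31,1
S28N,3.19,2.65,2.42,783.04,0
P112L,4.79,3.93,2.74,717.44,0
L35P,1.13,1.27,1.24,784.39,0
K60E,175.69,128.06,84.50,2753.69,1
V113I,1.58,1.21,1.06,804.55,0
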
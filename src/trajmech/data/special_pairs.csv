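variant,thr44_thr80_pct,asp116_ser118_pct
WT,51.38,62.18
K17I,96.87,95.31
S28N,82.51,74.27
P112L,53.66,69.24
L35P,84.59,89.36
K60E,49.92,61.76
V113I,50.36,63.15
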
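variant,donor_res,donor_name,acceptor_res,acceptor_name,occupancy_pct
WT,17,LYS,15,ASP,10.22
WT,15,ASP,46,ILE,4.47
WT,46,ILE,13,HIS,37.53
WT,13,HIS,44,THR,21.74
WT,44,THR,117,GLN,25.31
WT,117,GLN,116,ASP,15.57
WT,116,ASP,114,HIS,2.72
WT,114,HIS,106,ALA,27.33
WT,106,ALA,113,VAL,43.10
K17I,17,ILE,15,ASP,0.55
K17I,15,ASP,46,ILE,4.80
K17I,46,ILE,13,HIS,38.41
K17I,13,HIS,115,LEU,18.61
K17I,115,LEU,117,GLN,30.83
K17I,117,GLN,116,ASP,23.88
K17I,116,ASP,114,HIS,3.52
K17I,114,HIS,106,ALA,78.21
K17I,106,ALA,113,VAL,81.58
L35P-Leu115,35,PRO,40,LYS,10.12
L35P-Leu115,40,LYS,12,GLN,13.50
L35P-Leu115,12,GLN,13,HIS,6.42
L35P-Leu115,13,HIS,115,LEU,17.28
L35P-Leu115,115,LEU,117,GLN,19.84
L35P-Leu115,117,GLN,116,ASP,9.73
L35P-Leu115,116,ASP,114,HIS,8.94
L35P-Leu115,114,HIS,106,ALA,65.81
L35P-Leu115,106,ALA,113,VAL,63.15
L35P-Thr44,35,PRO,40,LYS,10.12
L35P-Thr44,40,LYS,12,GLN,13.50
L35P-Thr44,12,GLN,13,HIS,6.42
L35P-Thr44,13,HIS,44,THR,16.59
L35P-Thr44,44,THR,117,GLN,38.31
L35P-Thr44,117,GLN,116,ASP,9.73
L35P-Thr44,116,ASP,114,HIS,8.94
L35P-Thr44,114,HIS,106,ALA,65.81
L35P-Thr44,106,ALA,113,VAL,63.15
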
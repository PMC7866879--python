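variant,role,sequence,structure,pka,dynamics,substrate_zn,active_site,overall_printed
H1146A,damaging_control,damaging,benign,damaging,damaging,damaging,damaging,damaging
E1148A,damaging_control,damaging,damaging,damaging,damaging,damaging,damaging,damaging
H1060L,benign_control,benign,benign,benign,benign,benign,benign,benign
S912N,benign_control,benign,benign,benign,benign,benign,benign,benign
T1323A,benign_control,benign,benign,benign,benign,benign,benign,benign
N910S,query,benign,damaging,benign,damaging,benign,VUS,damaging
D980V,query,damaging,VUS,VUS,damaging,benign,damaging,damaging
S1025G,query,damaging,VUS,benign,damaging,damaging,VUS,damaging
C1153R,query,damaging,damaging,damaging,damaging,damaging,damaging,damaging
C1153Y,query,damaging,damaging,damaging,damaging,damaging,VUS,damaging
P1195L,query,VUS,damaging,damaging,damaging,damaging,VUS,damaging
L1200F,query,damaging,damaging,damaging,damaging,benign,benign,damaging
Q1212R,query,damaging,damaging,damaging,damaging,damaging,VUS,damaging
Q1248R,query,damaging,damaging,damaging,damaging,damaging,VUS,damaging
R1255W,query,damaging,damaging,damaging,damaging,damaging,damaging,damaging
R1351Q,query,benign,damaging,damaging,damaging,damaging,VUS,damaging
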
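resname,atom,charge,epsilon,rmin_half
*,N,-0.47,0.20,1.85
*,CA,0.07,0.02,2.275
*,C,0.51,0.11,2.00
*,O,-0.51,0.12,1.70
*,CB,-0.18,0.055,2.175
*,CG,-0.18,0.055,2.175
*,CD,-0.18,0.055,2.175
*,CE,-0.18,0.055,2.175
*,NZ,-0.30,0.20,1.85
*,OD1,-0.76,0.12,1.70
*,OD2,-0.76,0.12,1.70
*,OE1,-0.76,0.12,1.70
*,OE2,-0.76,0.12,1.70
*,SG,-0.23,0.45,2.00
*,OH,-0.54,0.1521,1.77
FE2,FE,2.00,0.000,0.65
ZN,ZN,2.00,0.25,1.09
OGA,C1,0.62,0.07,2.00
OGA,O1,-0.76,0.12,1.70
OGA,O2,-0.76,0.12,1.70
OGA,C2,0.62,0.07,2.00
OGA,O3,-0.76,0.12,1.70
OGA,O4,-0.76,0.12,1.70
OGA,C3,-0.18,0.055,2.175
OGA,C4,-0.18,0.055,2.175
OGA,C5,0.62,0.07,2.00
OGA,O5,-0.51,0.12,1.70
M3L,NZ,-0.60,0.20,1.85
M3L,CM1,0.25,0.078,2.05
M3L,CM2,0.25,0.078,2.05
M3L,CM3,0.25,0.078,2.05
*,*,0.00,0.10,2.00
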
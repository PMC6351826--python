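marker,probe,cluster_hint,direction
COL3A1,A_24_P935491,1,descending
FSP-1,A_23_P94800,1,descending
TGFB3,A_23_P88404,1,descending
TGFB2,A_24_P402438,1,descending
COL1A2,A_24_P277934,2,descending
ITGA1,A_33_P3353791,2,descending
DDR2,A_23_P452,2,descending
P4HA3,A_24_P290286,2,descending
THY1,A_33_P3280845,2,descending
FAP,A_23_P56746,2,descending
CD248,A_33_P3337485,2,descending
VIM,A_23_P161190,2,descending
COL1A1,A_33_P3304668,3,descending
ITGA5,A_23_P36562,3,descending
P4HA1,A_33_P3214481,3,descending
P4HA2,A_33_P3394933,3,descending
TGFB1,A_24_P79054,3,descending
HSP47,A_33_P3269203,,descending
CD34,A_23_P23829,,descending
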
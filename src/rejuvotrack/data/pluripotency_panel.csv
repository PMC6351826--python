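marker,probe,cluster_hint,direction
NANOG,A_23_P204640,1,ascending
REX1 (ZFP42),A_23_P395582,1,ascending
TRA-1-60/81 (PODXL),A_23_P215060,1,ascending
UTF1,A_33_P3294217,1,ascending
DPPA4,A_23_P380526,1,ascending
TDGF1 (CRIPTO),A_23_P366376,1,ascending
SALL4,A_23_P109072,1,ascending
LEFTY1,A_23_P160336,1,ascending
LEFTY2,A_23_P137573,1,ascending
DNMT3A,A_23_P154500,1,ascending
TFCP2L1,A_23_P5301,1,ascending
TERF1,A_23_P216149,2,ascending
DPPA5,A_32_P233950,2,ascending
TERT,A_23_P110851,2,ascending
ZIC3,A_23_P327910,2,ascending
LIN28a,A_23_P74895,2,ascending
LIN28b,A_33_P3220615,2,ascending
LECT1,A_23_P25587,2,ascending
DNMT3B,A_23_P28953,2,ascending
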
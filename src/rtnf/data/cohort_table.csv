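participant,sex,age,cag,cap,caudate_pct_icv,moca,tms,dcs,tfc
1,F,43,46,110,0.29,22,14,4,13
2,F,56,40,89,0.53,30,4,3,12
3,F,46,44,104,0.39,26,16,4,11
4,F,68,39,98,0.45,27,11,4,12
5,M,48,45,115,0.33,29,13,4,12
6,F,59,42,112,0.36,28,12,4,13
7,F,61,40,97,0.48,27,5,1,13
8,F,43,41,76,0.47,28,0,0,13
9,M,48,44,108,0.41,23,17,4,12
10,M,39,43,81,0.46,29,8,3,13
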
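organoid_id,condition,A1,A2,A3,B1,B2,C1,C2,D1,D2,D3,D4,D5,E1
11,0%,5,5,5,NA,NA,5,5,5,5,5,5,NA,5
58,0.1%,5,5,4,NA,NA,5,5,3,5,5,5,NA,5
50,0.25%,5,5,5,NA,NA,5,5,3,5,3,5,NA,4
52,0.5%,5,4,5,NA,NA,5,5,0,x,x,x,NA,x
51,1%,5,3,5,NA,NA,5,0,x,x,x,x,NA,x
17,5%,3,0,x,NA,NA,x,x,x,x,x,x,NA,x
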
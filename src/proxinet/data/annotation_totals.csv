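label,count,duration_s
CCCC1,604065,66472625
FFFF1,63009,4011285
FFFF0,50878,2716530
CCCC0,15347,1180295
FCFC1,2641,343315
CFCF1,2567,481575
FFCC0,1650,70735
CCFF0,1007,39095
FFFC0,350,37130
CFFF0,308,37795
FCFC0,213,31955
FFCF0,208,30240
FCFF0,196,22030
CFCF0,146,12860
FCCC0,90,5405
CFCC0,67,4695
CCCF0,52,3490
CCFC0,45,1935
CFFC0,50,2205
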
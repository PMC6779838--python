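sex,code,count
male,OPE,1460
male,DIA,2281
male,INA,1711
male,ACA,269
male,SCA,1647
male,PCA,935
male,BLO,537
male,DOD,1911
male,CUT,723
female,OPE,1704
female,DIA,2752
female,INA,1316
female,ACA,182
female,SCA,2422
female,PCA,649
female,BLO,834
female,DOD,2429
female,CUT,692
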
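pattern,focal,conditioned,male_count,male_order,female_count,female_order
I,OPE,DOD,898,1,1164,2
II,OPE,PCA,231,7,189,5
III,DIA,BLO,169,9,,
IV,DIA,CUT,368,4,477,4
V,DIA,ACA,112,11,87,8
VI,DIA,SCA,831,2,1346,1
VII,DIA,PCA,277,6,187,6
VIII,INA,CUT,179,8,,
IX,INA,ACA,132,10,73,9
X,INA,SCA,664,3,788,3
XI,INA,PCA,298,5,126,7
XII,ACA,BLO,,,23,11
XIII,ACA,OPE,49,11,33,10
XIV,ACA,DIA,94,8,61,8
XV,ACA,INA,77,10,39,9
XVI,SCA,BLO,114,7,402,3
XVII,SCA,OPE,360,3,410,2
XVIII,SCA,DIA,562,1,776,1
XIX,SCA,INA,412,2,390,4
XX,PCA,BLO,78,9,76,7
XXI,PCA,DOD,186,6,237,5
XXII,PCA,DIA,293,4,162,6
XXIII,PCA,INA,191,5,,
XXIV,BLO,OPE,95,9,171,6
XXV,BLO,DIA,156,7,306,4
XXVI,BLO,INA,138,8,121,8
XXVII,BLO,PCA,66,10,,
XXVIII,DOD,OPE,513,3,738,2
XXIX,DOD,DIA,688,1,1013,1
XXX,DOD,INA,555,2,508,3
XXXI,CUT,OPE,170,6,167,7
XXXII,CUT,DIA,272,4,280,5
XXXIII,CUT,INA,177,5,87,9
XXXIV,CUT,PCA,,,83,10
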
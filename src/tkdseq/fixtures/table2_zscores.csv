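sex,focal,conditioned,z
male,OPE,OPE,-14.28
male,OPE,DIA,-17.86
male,OPE,INA,-15.02
male,OPE,ACA,-2.37
male,OPE,SCA,-7.40
male,OPE,PCA,11.10
male,OPE,BLO,-7.47
male,OPE,DOD,48.49
male,OPE,CUT,1.36
male,DIA,OPE,-16.85
male,DIA,DIA,-21.99
male,DIA,INA,-19.21
male,DIA,ACA,8.93
male,DIA,SCA,33.18
male,DIA,PCA,7.54
male,DIA,BLO,6.72
male,DIA,DOD,-2.26
male,DIA,CUT,21.30
male,INA,OPE,-15.58
male,INA,DIA,-20.99
male,INA,INA,-17.71
male,INA,ACA,15.70
male,INA,SCA,30.70
male,INA,PCA,14.81
male,INA,BLO,0.05
male,INA,DOD,1.28
male,INA,CUT,7.38
male,ACA,OPE,3.21
male,ACA,DIA,6.88
male,ACA,INA,7.02
male,ACA,ACA,-2.55
male,ACA,SCA,-6.42
male,ACA,PCA,-4.92
male,ACA,BLO,0.76
male,ACA,DOD,-4.06
male,ACA,CUT,-3.52
male,SCA,OPE,13.60
male,SCA,DIA,17.50
male,SCA,INA,14.18
male,SCA,ACA,-6.70
male,SCA,SCA,-17.39
male,SCA,PCA,-12.82
male,SCA,BLO,4.91
male,SCA,DOD,-11.90
male,SCA,CUT,-9.15
male,PCA,OPE,1.71
male,PCA,DIA,10.43
male,PCA,INA,6.07
male,PCA,ACA,-4.66
male,PCA,SCA,-12.85
male,PCA,PCA,-9.29
male,PCA,BLO,5.74
male,PCA,DOD,3.09
male,PCA,CUT,-5.64
male,BLO,OPE,4.22
male,BLO,DIA,6.27
male,BLO,INA,8.06
male,BLO,ACA,-3.65
male,BLO,SCA,-8.15
male,BLO,PCA,3.71
male,BLO,BLO,-2.48
male,BLO,DOD,-7.09
male,BLO,CUT,-4.47
male,DOD,OPE,22.13
male,DOD,DIA,21.28
male,DOD,INA,20.95
male,DOD,ACA,-7.34
male,DOD,SCA,-18.95
male,DOD,PCA,-12.76
male,DOD,BLO,-6.20
male,DOD,DOD,-20.84
male,DOD,CUT,-10.44
male,CUT,OPE,9.95
male,CUT,DIA,13.37
male,CUT,INA,8.46
male,CUT,ACA,-4.01
male,CUT,SCA,-10.87
male,CUT,PCA,-1.72
male,CUT,BLO,-3.18
male,CUT,DOD,-11.42
male,CUT,CUT,-6.68
female,OPE,OPE,-14.29
female,OPE,DIA,-21.01
female,OPE,INA,-13.30
female,OPE,ACA,-1.87
female,OPE,SCA,-6.27
female,OPE,PCA,11.85
female,OPE,BLO,-11.27
female,OPE,DOD,54.75
female,OPE,CUT,-6.19
female,DIA,OPE,-20.76
female,DIA,DIA,-28.16
female,DIA,INA,-17.70
female,DIA,ACA,8.69
female,DIA,SCA,45.42
female,DIA,PCA,4.55
female,DIA,BLO,-1.34
female,DIA,DOD,-7.16
female,DIA,CUT,30.87
female,INA,OPE,-14.49
female,INA,DIA,-19.26
female,INA,INA,-12.24
female,INA,ACA,13.25
female,INA,SCA,39.81
female,INA,PCA,7.67
female,INA,BLO,-5.58
female,INA,DOD,-3.77
female,INA,CUT,1.58
female,ACA,OPE,2.28
female,ACA,DIA,4.53
female,ACA,INA,5.47
female,ACA,ACA,-1.61
female,ACA,SCA,-6.07
female,ACA,PCA,-3.11
female,ACA,BLO,3.52
female,ACA,DOD,-3.24
female,ACA,CUT,-2.55
female,SCA,OPE,7.09
female,SCA,DIA,16.05
female,SCA,INA,12.17
female,SCA,ACA,-6.26
female,SCA,SCA,-25.63
female,SCA,PCA,-12.16
female,SCA,BLO,22.90
female,SCA,DOD,-6.83
female,SCA,CUT,-8.72
female,PCA,OPE,-1.18
female,PCA,DIA,2.92
female,PCA,INA,1.89
female,PCA,ACA,-3.11
female,PCA,SCA,-12.51
female,PCA,PCA,-5.83
female,PCA,BLO,5.64
female,PCA,DOD,11.81
female,PCA,CUT,-3.74
female,BLO,OPE,7.26
female,BLO,DIA,12.48
female,BLO,INA,5.09
female,BLO,ACA,-3.21
female,BLO,SCA,-11.61
female,BLO,PCA,1.65
female,BLO,BLO,-0.80
female,BLO,DOD,-8.05
female,BLO,CUT,-4.80
female,DOD,OPE,28.67
female,DOD,DIA,28.54
female,DOD,INA,20.47
female,DOD,ACA,-5.59
female,DOD,SCA,-25.16
female,DOD,PCA,-10.88
female,DOD,BLO,-8.06
female,DOD,DOD,-25.64
female,DOD,CUT,-10.22
female,CUT,OPE,9.40
female,CUT,DIA,13.65
female,CUT,INA,2.72
female,CUT,ACA,-3.20
female,CUT,SCA,-11.75
female,CUT,PCA,8.73
female,CUT,BLO,-4.80
female,CUT,DOD,-9.76
female,CUT,CUT,-6.24
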
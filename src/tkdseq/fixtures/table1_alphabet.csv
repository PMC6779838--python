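code,label,tactical_class
OPE,Opening,attack
DIA,Direct attack,attack
INA,Indirect attack,attack
ACA,Anticipated counterattack,counterattack
SCA,Simultaneous counterattack,counterattack
PCA,Posterior counterattack,counterattack
BLO,Block,defense
DOD,Dodge,defense
CUT,Cut,defense
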
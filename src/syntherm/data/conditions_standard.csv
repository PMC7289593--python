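species,activity,unit
CH4,1.0,atm
H2,1.0,atm
HCO3-,1.0,M
acetate-,1.0,M
SO4-2,1.0,M
H2S,1.0,M
Fe+2,1.0,M
NO3-,1.0,M
NO2-,1.0,M
PCE,1.0,M
TCE,1.0,M
cDCE,1.0,M
DCA,1.0,M
ethene,1.0,M
MCB,1.0,M
benzene,1.0,M
2-CP,1.0,M
phenol,1.0,M
Cl-,1.0,M
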
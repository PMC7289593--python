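name,phase,charge,henry_mol_m3_Pa
CH4,g,0,1.4e-05
H2,g,0,7.8e-06
H2O,w,0,
H+,aq,1,
HCO3-,aq,-1,
acetate-,aq,-1,
SO4-2,aq,-2,
H2S,aq,0,
Fe(OH)3,s,0,
Fe+2,aq,2,
NO3-,aq,-1,
NO2-,aq,-1,
PCE,aq,0,
TCE,aq,0,
cDCE,aq,0,
DCA,aq,0,
ethene,aq,0,
MCB,aq,0,
benzene,aq,0,
2-CP,aq,0,
phenol,aq,0,
Cl-,aq,-1,
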
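id,equation,dg0_prime_kj,ref_species,donor,acceptor,n_electrons
aom_sulfate,CH4(g) + SO4-2(aq) + H+(aq) -> HCO3-(aq) + H2S(aq) + H2O(w),-16.5,CH4,CH4,SO4-2,8
aom_iron,CH4(g) + 8 Fe(OH)3(s) + 15 H+(aq) -> HCO3-(aq) + 8 Fe+2(aq) + 21 H2O(w),46.2,CH4,CH4,Fe(OH)3,8
aom_2cp,CH4(g) + 4 2-CP(aq) + 3 H2O(w) -> HCO3-(aq) + 4 phenol(aq) + 5 H+(aq) + 4 Cl-(aq),-476.3,CH4,CH4,2-CP,8
aom_mcb,CH4(g) + 4 MCB(aq) + 3 H2O(w) -> HCO3-(aq) + 4 benzene(aq) + 5 H+(aq) + 4 Cl-(aq),-477.9,CH4,CH4,MCB,8
aom_nitrate,CH4(g) + 4 NO3-(aq) -> HCO3-(aq) + 4 NO2-(aq) + H2O(w) + H+(aq),-510.7,CH4,CH4,NO3-,8
aom_pce,CH4(g) + 4 PCE(aq) + 3 H2O(w) -> HCO3-(aq) + 4 TCE(aq) + 5 H+(aq) + 4 Cl-(aq),-557.9,CH4,CH4,PCE,8
aom_tce,CH4(g) + 4 TCE(aq) + 3 H2O(w) -> HCO3-(aq) + 4 cDCE(aq) + 5 H+(aq) + 4 Cl-(aq),-539.9,CH4,CH4,TCE,8
aom_dca,CH4(g) + 4 DCA(aq) + 3 H2O(w) -> HCO3-(aq) + 4 ethene(aq) + 9 H+(aq) + 8 Cl-(aq),-853.5,CH4,CH4,DCA,8
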
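id,equation,dg0_prime_kj,ref_species,donor,acceptor,n_electrons
aom,CH4(g) + 3 H2O(w) -> HCO3-(aq) + 4 H2(g) + H+(aq),135.4,CH4,CH4,,8
acetogenesis,2 HCO3-(aq) + 4 H2(g) + H+(aq) -> acetate-(aq) + 4 H2O(w),-104.2,acetate-,H2,HCO3-,8
methanogenesis,HCO3-(aq) + 4 H2(g) + H+(aq) -> CH4(g) + 3 H2O(w),-135.4,CH4,H2,HCO3-,8
sulfate_reduction,SO4-2(aq) + 4 H2(g) + 2 H+(aq) -> H2S(aq) + 4 H2O(w),-151.9,SO4-2,H2,SO4-2,8
iron_reduction,2 Fe(OH)3(s) + 4 H+(aq) + H2(g) -> 2 Fe+2(aq) + 6 H2O(w),-44.6,H2,H2,Fe(OH)3,2
nitrate_reduction,NO3-(aq) + H2(g) -> NO2-(aq) + H2O(w),-158.1,NO3-,H2,NO3-,2
pce_dechlorination,PCE(aq) + H2(g) -> TCE(aq) + H+(aq) + Cl-(aq),-173.3,PCE,H2,PCE,2
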
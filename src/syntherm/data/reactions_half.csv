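id,equation,dg0_prime_kj,ref_species,donor,acceptor,n_electrons
half_pce,PCE(aq) + H2(g) -> TCE(aq) + H+(aq) + Cl-(aq),-173.3,H2,H2,PCE,2
half_tce,TCE(aq) + H2(g) -> cDCE(aq) + H+(aq) + Cl-(aq),-168.825,H2,H2,TCE,2
half_mcb,MCB(aq) + H2(g) -> benzene(aq) + H+(aq) + Cl-(aq),-153.325,H2,H2,MCB,2
half_2cp,2-CP(aq) + H2(g) -> phenol(aq) + H+(aq) + Cl-(aq),-152.925,H2,H2,2-CP,2
half_dca,DCA(aq) + H2(g) -> ethene(aq) + 2 H+(aq) + 2 Cl-(aq),-247.225,H2,H2,DCA,2
half_sulfate,1/4 SO4-2(aq) + H2(g) + 1/2 H+(aq) -> 1/4 H2S(aq) + H2O(w),-38.0,H2,H2,SO4-2,2
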
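# Textbook SMILES for seven FDA-approved anticancer drugs (SMILES<tab>id)
Nc1ccn([C@@H]2O[C@H](CO)[C@@H](O)[C@@H]2O)c(=O)n1	cytarabine
Nc1ccn([C@@H]2O[C@H](CO)[C@H](O)C2(F)F)c(=O)n1	gemcitabine
ClCCN(N=O)C(=O)NCCCl	carmustine
ClCCN(N=O)C(=O)NC1CCCCC1	lomustine
CN(C)C/C=C/C(=O)Nc1cc2c(Nc3ccc(F)c(Cl)c3)ncnc2cc1O[C@H]1CCOC1	afatinib
COc1cc2ncnc(Nc3ccc(F)c(Cl)c3)c2cc1NC(=O)/C=C/CN1CCCCC1	dacomitinib
CCOc1cc2ncc(C#N)c(Nc3ccc(OCc4ccccn4)c(Cl)c3)c2cc1NC(=O)/C=C/CN(C)C	neratinib
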
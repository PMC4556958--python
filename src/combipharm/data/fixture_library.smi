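c1ccccc1 benzene
Cc1ccccc1 toluene
CCCCCC hexane
CC(=O)O acetic_acid
CCCN propylamine
Oc1ccccc1 phenol
NC(=O)c1ccccc1 benzamide
c1ccncc1 pyridine
CN1CCCCC1 n_methylpiperidine
CC(C)Cc1ccc(cc1)C(C)C(=O)O arylpropionic_acid
Cc1ccc(Cl)cc1 chlorotoluene
OC(=O)c1ccccc1 benzoic_acid
c1cnc[nH]1 imidazole
CN(C)CCOC(c1ccccc1)c1ccccc1 diaryl_aminoether
CN(C)C(=N)N=C(N)N biguanide
CC(C)NCC(O)COc1ccc2ccccc2c1 aryloxy_propanolamine
NCCS(=O)(=O)O aminoethanesulfonic_acid
CC#N acetonitrile
NC1CCCCC1 cyclohexylamine
Nc1ccc(cc1)C(=O)O aminobenzoic_acid
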
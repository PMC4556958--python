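mol_id,label
benzene,inactive
toluene,inactive
hexane,inactive
acetic_acid,inactive
propylamine,inactive
phenol,inactive
benzamide,inactive
pyridine,inactive
n_methylpiperidine,active
arylpropionic_acid,inactive
chlorotoluene,inactive
benzoic_acid,inactive
imidazole,inactive
diaryl_aminoether,active
biguanide,active
aryloxy_propanolamine,active
aminoethanesulfonic_acid,inactive
acetonitrile,inactive
cyclohexylamine,inactive
aminobenzoic_acid,inactive
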
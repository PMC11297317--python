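raw_location	category
cytoplasm	Cytoplasm
cytosol	Cytoplasm
cytoplasmic bodies	Cytoplasm
aggresome	Cytoplasm
rods & rings	Cytoplasm
centrosome	Cytoplasm
centriolar satellite	Cytoplasm
microtubules	Cytoplasm
microtubule ends	Cytoplasm
cytokinetic bridge	Cytoplasm
midbody	Cytoplasm
midbody ring	Cytoplasm
mitotic spindle	Cytoplasm
actin filaments	Cytoplasm
intermediate filaments	Cytoplasm
cleavage furrow	Cytoplasm
endoplasmic reticulum	Endoplasmic reticulum
golgi apparatus	Golgi apparatus
mitochondria	Mitochondria
plasma membrane	Plasma membrane
cell junctions	Plasma membrane
focal adhesion sites	Plasma membrane
nuclear	Nuclear
nucleus	Nuclear
nucleoplasm	Nuclear
nuclear membrane	Nuclear
nuclear bodies	Nuclear
nuclear speckles	Nuclear
nucleoli	Nuclear
nucleoli fibrillar center	Nuclear
nucleoli rim	Nuclear
kinetochore	Nuclear
mitotic chromosome	Nuclear
vesicles	Vesicles
endosomes	Vesicles
lysosomes	Vesicles
peroxisomes	Vesicles
lipid droplets	Vesicles
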
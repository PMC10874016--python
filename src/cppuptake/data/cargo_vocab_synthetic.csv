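label
FITC
fluorescein
carboxyfluorescein
rhodamine
TAMRA
Dil
Cy3
Cy5
Cy5.5
Alexa488
Alexa555
Alexa647
BODIPY
NBD
dansyl
coumarin
Texas-red
GFP-fluorophore
quantum-dot
DyLight650
siRNA
plasmid-DNA
antisense-oligonucleotide
miRNA
mRNA
PNA
morpholino
CpG-oligonucleotide
shRNA-vector
aptamer
GFP
streptavidin
BSA
antibody-IgG
Fab-fragment
beta-galactosidase
luciferase
insulin
cytochrome-c
peptide-epitope
enzyme-cargo
doxorubicin
methotrexate
paclitaxel
cisplatin
biotin
folate
chlorambucil
camptothecin
curcumin
cyclosporine
gold-nanoparticle
iron-oxide-nanoparticle
silica-nanoparticle
liposome
micelle
dendrimer
PLGA-nanoparticle
polymer-conjugate
PEG-chain
MRI-contrast-agent
radiolabel-chelate
none
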
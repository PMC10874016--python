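raw,canonical,relative
MFI,MFI,0
mfi,MFI,0
mean fluorescence intensity,MFI,0
Mean Fluorescence Intensity,MFI,0
geometric MFI,MFI,0
a.u.,arbitrary-units,0
AU,arbitrary-units,0
arbitrary units,arbitrary-units,0
RFU,RFU,0
relative fluorescence units,RFU,0
fluorescence intensity,fluorescence-intensity,0
nmol,nmol,0
pmol,pmol,0
nmol/mg protein,nmol-per-mg-protein,0
pmol/10^6 cells,pmol-per-1e6-cells,0
uM internalized,uM-internalized,0
% of control,percent-of-control,1
percent of control,percent-of-control,1
fold over control,fold-over-control,1
fold change,fold-over-control,1
relative uptake,relative-uptake,1
% uptake,percent-uptake,1
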
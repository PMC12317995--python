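# SYNTHETIC example region definition in a Chothia-like numbering style.
# Non-normative: real projects must supply definitions matching their own
# numbering scheme. Columns: label,chain,start,end (inclusive residue range).
label,chain,start,end
Fv,H,1,120
Fv,L,1,110
CDRH1,H,26,32
CDRH2,H,52,56
CDRH3,H,95,102
CDRL1,L,24,34
CDRL2,L,50,56
CDRL3,L,89,97
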
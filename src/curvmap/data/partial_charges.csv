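# Coarse side-chain/terminus partial charges (elementary charge units) at
# formulation pH ~6: unit charges split over the terminal atoms of charged
# groups. All unlisted atoms carry zero charge. Users needing force-field
# charges should supply a PQR file instead.
residue,atom_name,charge
ARG,NH1,0.5
ARG,NH2,0.5
LYS,NZ,1.0
ASP,OD1,-0.5
ASP,OD2,-0.5
GLU,OE1,-0.5
GLU,OE2,-0.5
ANY,OXT,-1.0
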
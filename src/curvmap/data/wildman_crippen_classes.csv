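# Atomic logP contributions by coarse atom class (aromatic/aliphatic/carbonyl
# carbon, polar N/O, sulfur, hydrogens on C vs heteroatoms). Values are
# representative published per-class contributions; typing is heuristic
# (residue + atom-name based) with element-level fallback, since no bonded
# topology is available from a bare PDB.
atom_class,value
C_ALIPHATIC,0.1441
C_AROMATIC,0.1581
C_CARBONYL,-0.2783
N_POLAR,-0.6027
O_HYDROXYL,-0.2893
O_CARBONYL,-0.1526
S_ANY,0.6482
H_ON_C,0.1230
H_POLAR,-0.2677
P_ANY,0.8612
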
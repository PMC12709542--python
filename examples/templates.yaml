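# Residue-template configuration for foldhelix (`--templates` / load_templates).
#
# Each top-level key defines (or overrides) a residue template. The built-in
# templates use the synthetic pseudo-atom chemistry (ring atoms C1..C6,
# backbone atoms N1..N6, phosphonate P/O1-O3 with donor hydrogen H1); real
# force-field setups can remap every atom group here without touching code.
#
# Dihedral quadruples use ATOM@OFFSET entries, where OFFSET is the residue
# offset (-1, 0 or +1) relative to the residue carrying the template. The
# six labels alpha..zeta (Greek single letters accepted) cover one mQQ
# repeat unit; gamma and delta are the labels that shift during kinks.

mQ:
  ring_atoms: [C1, C2, C3, C4, C5, C6]
  side_chain_atoms: [P, O1, O2, O3, H1]
  phosphorus_atom: P
  hbond_donor_hydrogens: [H1]
  hbond_acceptor_oxygens: [O1, O2, O3]
  dihedrals:
    alpha:   [C2@0, C1@0, N1@0, N2@0]
    beta:    [C3@0, C2@0, C1@0, N3@0]
    gamma:   [C1@0, N1@0, C1@+1, N4@+1]
    delta:   [N1@0, C1@+1, N1@+1, N5@+1]
    epsilon: [C2@0, C1@0, C1@+1, C2@+1]
    zeta:    [C3@0, C1@0, N1@+1, C4@+1]

Q4:
  ring_atoms: [C1, C2, C3, C4, C5, C6]
  side_chain_atoms: [P, O1, O2, O3, H1]
  phosphorus_atom: P
  hbond_donor_hydrogens: [H1]
  hbond_acceptor_oxygens: [O1, O2, O3]
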
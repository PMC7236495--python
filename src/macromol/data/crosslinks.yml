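id: crosslinks
name: Ontology of common protein crosslinks (curated fixture)
types:
  disulfide:
    name: disulfide bond
    l_bond_atoms:
    - S7
    l_displaced_atoms:
    - H7
    r_bond_atoms:
    - S7
    r_displaced_atoms:
    - H7
    l_allowed_residues:
    - C
    r_allowed_residues:
    - C
    comments: R-S-S-R from two thiols; loses two H
  isopeptide-K-G:
    name: isopeptide bond, lysine N(zeta) to glycine carboxyl (pupylation-style)
    l_bond_atoms:
    - N10
    l_displaced_atoms:
    - H10
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    l_allowed_residues:
    - K
    r_allowed_residues:
    - G
    comments: loses H2O
  thioester-C-G:
    name: thioester bond, cysteine S(gamma) to glycine carboxyl
    l_bond_atoms:
    - S7
    l_displaced_atoms:
    - H7
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    l_allowed_residues:
    - C
    r_allowed_residues:
    - G
    comments: loses H2O
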
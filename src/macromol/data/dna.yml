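id: dna
name: DNA residue alphabet (curated fixture)
type: DNA
residues:
  A:
    id: damp
    name: 2'-deoxyadenosine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=NC3=C2N=CN=C3N)CC1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O22
    r_displaced_atoms:
    - H22
    xrefs:
    - - PDB-CCD
      - DA
  C:
    id: dcmp
    name: 2'-deoxycytidine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=CC(N)=NC2=O)CC1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O20
    r_displaced_atoms:
    - H20
    xrefs:
    - - PDB-CCD
      - DC
  G:
    id: dgmp
    name: 2'-deoxyguanosine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=NC3=C2N=C(N)NC3=O)CC1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O23
    r_displaced_atoms:
    - H23
    xrefs:
    - - PDB-CCD
      - DG
  T:
    id: dtmp
    name: thymidine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=C(C)C(=O)NC2=O)CC1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O21
    r_displaced_atoms:
    - H21
    xrefs:
    - - PDB-CCD
      - DT
  5mC:
    id: 5mdcmp
    name: 5-methyl-2'-deoxycytidine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=C(C)C(N)=NC2=O)CC1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O21
    r_displaced_atoms:
    - H21
    base_monomers:
    - C
    xrefs:
    - - PDB-CCD
      - 5CM
    - - DNAmod
      - 5mC
  6mA:
    id: 6mdamp
    name: N6-methyl-2'-deoxyadenosine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=NC3=C2N=CN=C3NC)CC1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O23
    r_displaced_atoms:
    - H23
    base_monomers:
    - A
    xrefs:
    - - PDB-CCD
      - 6MA
    - - DNAmod
      - 6mA
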
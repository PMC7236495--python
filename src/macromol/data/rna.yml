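id: rna
name: RNA residue alphabet (curated fixture)
type: RNA
residues:
  A:
    id: amp
    name: adenosine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=NC3=C2N=CN=C3N)C(O)C1O
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
      - A
  C:
    id: cmp
    name: cytidine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=CC(N)=NC2=O)C(O)C1O
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
      - C
  G:
    id: gmp
    name: guanosine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=NC3=C2N=C(N)NC3=O)C(O)C1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O24
    r_displaced_atoms:
    - H24
    xrefs:
    - - PDB-CCD
      - G
  U:
    id: ump
    name: uridine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=CC(=O)NC2=O)C(O)C1O
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
      - U
  9U:
    id: psi-ump
    name: pseudouridine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(C2=CNC(=O)NC2=O)C(O)C1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O21
    r_displaced_atoms:
    - H21
    base_monomers:
    - U
    xrefs:
    - - PDB-CCD
      - PSU
    - - MODOMICS
      - 9U
  74U:
    id: s4-ump
    name: 4-thiouridine 5'-monophosphate
    structure: OP(O)(=O)OCC1OC(N2C=CC(=S)NC2=O)C(O)C1O
    l_bond_atoms:
    - P2
    l_displaced_atoms:
    - O1
    r_bond_atoms:
    - O21
    r_displaced_atoms:
    - H21
    base_monomers:
    - U
    xrefs:
    - - PDB-CCD
      - 4SU
    - - MODOMICS
      - 74U
  m7G:
    id: m7g-cap
    name: 7-methylguanosine 5' cap (as 5'-diphosphate)
    structure: OP(O)(=O)OP(O)(=O)OCC1OC(N2C=[N+](C)C3=C2N=C(N)NC3=O)C(O)C1O
    r_bond_atoms:
    - O1
    r_displaced_atoms:
    - H1
    xrefs:
    - - PDB-CCD
      - M7G
    - - MODOMICS
      - m7G
    comments: left cap; bonding through the terminal phosphate O yields the natural
      5'-5' triphosphate bridge to the first residue
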
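id: protein
name: Protein residue alphabet (curated fixture)
type: protein
residues:
  A:
    id: ala
    name: alanine
    structure: NC(C(O)=O)C
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - ALA
  R:
    id: arg
    name: arginine
    structure: NC(C(O)=O)CCCNC(N)=N
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - ARG
  N:
    id: asn
    name: asparagine
    structure: NC(C(O)=O)CC(N)=O
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - ASN
  D:
    id: asp
    name: aspartate
    structure: NC(C(O)=O)CC(O)=O
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - ASP
  C:
    id: cys
    name: cysteine
    structure: NC(C(O)=O)CS
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - CYS
  E:
    id: glu
    name: glutamate
    structure: NC(C(O)=O)CCC(O)=O
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - GLU
  Q:
    id: gln
    name: glutamine
    structure: NC(C(O)=O)CCC(N)=O
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - GLN
  G:
    id: gly
    name: glycine
    structure: NCC(O)=O
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - GLY
  H:
    id: his
    name: histidine
    structure: NC(C(O)=O)CC1=CNC=N1
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - HIS
  I:
    id: ile
    name: isoleucine
    structure: NC(C(O)=O)C(C)CC
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - ILE
  L:
    id: leu
    name: leucine
    structure: NC(C(O)=O)CC(C)C
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - LEU
  K:
    id: lys
    name: lysine
    structure: NC(C(O)=O)CCCCN
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - LYS
  M:
    id: met
    name: methionine
    structure: NC(C(O)=O)CCSC
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - MET
  F:
    id: phe
    name: phenylalanine
    structure: NC(C(O)=O)CC1=CC=CC=C1
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - PHE
  P:
    id: pro
    name: proline
    structure: OC(=O)C1CCCN1
    l_bond_atoms:
    - N8
    l_displaced_atoms:
    - H8
    r_bond_atoms:
    - C2
    r_displaced_atoms:
    - O1
    xrefs:
    - - PDB-CCD
      - PRO
  S:
    id: ser
    name: serine
    structure: NC(C(O)=O)CO
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - SER
  T:
    id: thr
    name: threonine
    structure: NC(C(O)=O)C(O)C
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - THR
  W:
    id: trp
    name: tryptophan
    structure: NC(C(O)=O)CC1=CNC2=CC=CC=C12
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - TRP
  Y:
    id: tyr
    name: tyrosine
    structure: NC(C(O)=O)CC1=CC=C(O)C=C1
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - TYR
  V:
    id: val
    name: valine
    structure: NC(C(O)=O)C(C)C
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    xrefs:
    - - PDB-CCD
      - VAL
  U:
    id: sec
    name: selenocysteine
    structure: NC(C(O)=O)C[SeH]
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    aliases:
    - SEC
    xrefs:
    - - PDB-CCD
      - SEC
    - - RESID
      - AA0022
  SEP:
    id: pser
    name: O-phosphoserine
    structure: NC(C(O)=O)COP(O)(O)=O
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    base_monomers:
    - S
    xrefs:
    - - PDB-CCD
      - SEP
    - - RESID
      - AA0037
  TPO:
    id: pthr
    name: O-phosphothreonine
    structure: NC(C(O)=O)C(OP(O)(O)=O)C
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    base_monomers:
    - T
    xrefs:
    - - PDB-CCD
      - TPO
    - - RESID
      - AA0038
  PTR:
    id: ptyr
    name: O-phosphotyrosine
    structure: NC(C(O)=O)CC1=CC=C(OP(O)(O)=O)C=C1
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    r_bond_atoms:
    - C3
    r_displaced_atoms:
    - O4
    base_monomers:
    - Y
    xrefs:
    - - PDB-CCD
      - PTR
    - - RESID
      - AA0039
  HYP:
    id: hyp
    name: 4-hydroxyproline
    structure: OC(=O)C1CC(O)CN1
    l_bond_atoms:
    - N9
    l_displaced_atoms:
    - H9
    r_bond_atoms:
    - C2
    r_displaced_atoms:
    - O1
    base_monomers:
    - P
    xrefs:
    - - PDB-CCD
      - HYP
    - - RESID
      - AA0030
  AC:
    id: ac-cap
    name: amino-terminal acetyl cap
    structure: CC(O)=O
    r_bond_atoms:
    - C2
    r_displaced_atoms:
    - O3
    xrefs:
    - - PDB-CCD
      - ACE
    - - RESID
      - AA0041
    comments: 'left cap: no left bond atoms; acylates the amino terminus'
  NH2:
    id: nh2-cap
    name: carboxy-terminal amide cap
    structure: N
    l_bond_atoms:
    - N1
    l_displaced_atoms:
    - H1
    xrefs:
    - - PDB-CCD
      - NH2
    comments: 'right cap: no right bond atoms; amidates the carboxy terminus'
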
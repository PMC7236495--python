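# macromol

Concrete, concise descriptions of the primary structure of DNA, RNA, proteins,
and complexes — including the chemistry the plain one-letter sequence formats
cannot express: non-canonical (modified) residues, 5′/N-terminal caps,
crosslinks such as disulfide and isopeptide bonds, nicks (missing backbone
bonds), and circularity.

The package is aimed at omics researchers who need to exchange and
quality-control proteoform or modified-nucleotide annotations, and at systems
and synthetic biologists who need species in their networks to have concrete,
element-balanced molecular structures.

## The representation

Macromolecules are described in three layers:

1. **Complexes** are bags of subunits with stoichiometries plus inter-subunit
   crosslinks: `2 * pep | x-link: [type: disulfide | l: pep(1)-2 | r: pep(2)-2]`.
2. **Polymers** are sequences of residues with nicks (`:`), intra-chain
   crosslinks, circularity, and uncertainty metadata: `AC{SEC}`, `AA:GG`,
   `ACGT | circular`.
3. **Residues** are molecular graphs (stored as SMILES) annotated with the
   atoms that form bonds with the preceding/following residue and the atoms
   displaced when those bonds form. An amino acid loses H from its amine N and
   OH from its carboxyl C per peptide bond — one water per backbone bond; a
   disulfide loses one H per cysteine.

A hierarchical coordinate addresses any atom: subunit id and copy number →
residue position (1-based) → element and atom index in the residue's stored
SMILES order (`pep(1)-2S7` = the sulfur, atom 7, of residue 2 of copy 1 of
`pep`). Packaged alphabets cover the canonical DNA/RNA/protein residues plus a
curated set of modified residues (phosphoserine/-threonine/-tyrosine,
selenocysteine, 4-hydroxyproline, 5-methyl-dC, N6-methyl-dA, pseudouridine,
4-thiouridine), caps (N-terminal acetyl, C-terminal amide, 7-methylguanosine
5′ cap), and a crosslink ontology (disulfide, isopeptide, thioester); users
can load their own YAML alphabets or define residues and crosslinks inline.

Given a description, the package validates it (nine semantic rules: cap
placement, bondability, atom resolution, hydrogen availability, coordinate
ranges, crosslink compatibility, double-consumed atoms, ...), assembles it
into an atom-level molecular graph, and computes its chemical formula,
molecular weight (IUPAC standard atomic weights), and net formal charge. It
also compares molecules (complexes up to permutation of interchangeable
subunit copies), exports SMILES and canonical IUPAC/IUBMB sequences or FASTA,
and checks modified polymers against reference sequences — catching errors
like a phosphoserine annotated at a tyrosine position or a site beyond the
end of the parent sequence.

## Worked example

```python
from macromol import (
    packaged_alphabet, packaged_ontology, parse_polymer, parse_complex,
    canonical_sequence, semantics,
)

protein = packaged_alphabet("protein")
onto = packaged_ontology()

pep = parse_polymer("AC{SEC}", protein, onto)     # Ala-Cys-selenocysteine
print(canonical_sequence(pep))                    # -> ACU
print(semantics.get_formula(pep, onto))           # -> C9H17N3O4SSe
print(round(semantics.get_mol_weight(pep, onto), 2))  # -> 342.28

dimer = parse_complex(
    "2 * pep | x-link: [type: disulfide | l: pep(1)-2 | r: pep(2)-2]",
    {"pep": pep}, onto,
)
print(semantics.validate_complex(dimer, onto).ok)     # -> True
print(semantics.get_formula(dimer, onto))             # -> C18H32N6O8S2Se2
print(round(semantics.get_mol_weight(dimer, onto), 2))  # -> 682.55
```

The tripeptide weighs 342.28 Da (three free amino acids minus two waters for
the peptide bonds); the disulfide-linked homodimer weighs 682.55 Da (two
copies minus two hydrogens for the S–S bond) and is electrically neutral.

The same operations are available from the shell:

```bash
$ echo 'AC{SEC}' > pep.txt
$ macromol props pep.txt
{
  "pep": {
    "charge": 0,
    "formula": "C9H17N3O4SSe",
    "mol_weight": 342.28
  }
}
$ macromol export pep.txt --format canonical-seq
ACU
```

`macromol validate` exits 0 only on clean input, 1 on validation errors, 2 on
parse failures; `macromol qc --ref ref.fasta --offset 1` checks annotations
against reference sequences with an initiator-methionine-style coordinate
shift; `macromol gen-corpus` emits seeded corpora of clean or
deliberately-defective descriptions.

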
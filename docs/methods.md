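# Methods

## Model of primary structure

A macromolecule is represented in three layers. A *complex* is a multiset of
subunits — each a polymer or a small molecule — with integer stoichiometries
and a set of inter-subunit crosslinks. A *polymer* is an ordered sequence of
residue occurrences together with a set of nicks (positions after which no
backbone bond exists), a set of intra-chain crosslinks, a circularity flag,
and uncertainty metadata (observed-but-uninterpreted extra mass/charge, and
per-residue position ranges). A *residue* is a concrete molecular graph plus
four atom lists: the atoms that bond to the preceding (left) and following
(right) residue, and the atoms displaced when each of those bonds forms.
Caps are simply residues with an empty left or right bond-atom list, so the
same machinery covers 5′ caps and terminal modifications.

This decomposition is closed under the chemistry it models: any DNA, RNA, or
protein — linear, circular, nicked, branched by crosslinks, or assembled into
a covalent complex — maps to one molecular graph, and two descriptions that
assemble to the same graph have the same formula, weight, and charge.

### Bond chemistry conventions

Amino acids are stored as free amino acids; the left bond atom is the
backbone amine N (displacing one of its hydrogens) and the right bond atom is
the carboxyl C (displacing the hydroxyl O, which takes its hydrogen with it).
Each peptide bond therefore removes exactly one water. Nucleotides are stored
as 5′-monophosphates; the left bond atom is the phosphate P (displacing one
P–OH oxygen) and the right bond atom is the 3′ oxygen (displacing its
hydrogen), so each phosphodiester bond likewise removes one water. Crosslinks
declare the same four lists relative to the two residues they join; the
packaged disulfide bonds S to S displacing one H on each side. All
inter-residue and crosslink bonds are single bonds; when a bond specification
lists several atoms per side, pairs are matched by list order.

Displaced hydrogens are implicit hydrogens: they decrement the parent atom's
implicit-hydrogen count. Displaced heavy atoms are deleted together with
their own hydrogens. A charge delta on a bond atom or on a displaced-hydrogen
parent is applied when the bond forms; a charge delta on a deleted atom would
be meaningless and is ignored (the packaged fixtures use zero deltas
throughout).

## Atom coordinates and the SMILES core

Every atom coordinate in the toolkit is "element + 1-based position in the
stored SMILES order of the residue's structure". To make that order an
invariant of the data rather than of a third-party canonicalizer, the package
carries its own SMILES subset reader/writer: atoms are numbered in order of
first appearance in the stored string, implicit hydrogens are not numbered
(they are addressed as element `H` on their heavy atom), and the writer emits
depth-first from atom 1 with neighbors in ascending index, so serialization
is deterministic. The subset covers organic-subset atoms, bracket atoms with
charges and explicit hydrogen counts (bracket isotopes parse and are ignored
with a warning), bond orders 1–3, branches, ring closures, and dot-separated
components. Aromatic (lowercase) input is accepted and kekulized by a
backtracking perfect matching of double bonds over each aromatic system —
atoms that already carry an explicit double bond (e.g. exocyclic carbonyls),
pyrrole-type nitrogens, and aromatic O/S take no matching edge — and input
that admits no matching is rejected. Stereochemistry, isotope semantics,
tautomer/protonation enumeration, and monoisotopic masses are out of scope;
charges are the formal charges of the stored structures.

Molecular weights use a packaged table of IUPAC standard (average) atomic
weights; weight comparisons use a 0.01 Da tolerance. Formulas are rendered in
Hill order. The test suite cross-checks the formula, mass summation, and
charge of every packaged residue against rdkit as an independent toolkit;
because rdkit's periodic table lags current IUPAC values for some elements
(selenium differs by 0.011 Da), the mass cross-check is performed on a common
atomic-weight basis at 0.01 Da, with an absolute guard band of 0.02 Da.

## Grammars

The polymer grammar is a sequence of units — one-letter codes, brace-quoted
multi-character codes, bracketed inline residue definitions, and `:` for
nicks — followed by `|`-separated attributes (`circular`, `x-link: [...]`,
`extra: [mass: ... | charge: ...]`, `comments: "..."`). Whitespace is
insignificant outside quotes; the grammar is case-sensitive; residue
positions count residues, not nicks. An uncertainly-located residue is
written at a concrete anchor position with a `position: lo-hi` range, which
keeps the sequence length well defined. Any plain IUPAC/IUBMB string over an
alphabet's canonical codes is a valid description whose canonical sequence is
itself, so the grammar is backward compatible with ordinary sequence
notation. The complex grammar is `n * id + ...` plus crosslink attributes
whose slots are `id(copy)-residue`, optionally extended with an atom
coordinate for explicit-atom crosslinks. Subunit structures are supplied out
of band (a mapping or YAML manifest), mirroring the layering of the model.
Both parsers are hand-written recursive-descent scanners that report
line/column positions and expected tokens on failure.

## Validation

Nine rules make "describes a buildable molecule" checkable: V1 adjacent
bondability, V2 cap placement (chain ends or nick-adjacent only), V3 circular
closure, V4 atom-reference resolution (element and index), V5 displaced-
hydrogen availability (totalled over all bonds touching an atom), V6
crosslink coordinates in range, V7 crosslink residue-type compatibility with
the ontology entry, V8 no atom consumed by two bonds, V9 position-range
sanity. Findings are reported, never raised; an empty error list is exactly
the condition under which assembly succeeds. A crosslink spanning a nick is
accepted with a warning (the chemistry is well defined; the topology is
unusual), as is a degenerate single-copy, crosslink-free "complex". A
misplaced cap generally trips both V1 (its neighbor pair cannot bond) and V2
(the cap itself); both findings are reported at their own locations.

Reference-sequence QC maps each residue to its base monomers (e.g.
phosphoserine → S) and compares against a canonical reference with an
optional coordinate offset for initiator-methionine-style shifts; residues
with no base monomers (unknown origin, caps) are wildcards that warn rather
than fail.

## Equality and difference

Two polymers are equal when their normalized forms agree: alias codes
collapse to primary codes, inline residues that are structurally identical to
an alphabet entry (same serialized structure, bond lists, and base monomers)
collapse to its code, and crosslinks are compared as sorted sets. Complexes
are equal up to permutation of interchangeable subunit copies; the search is
exhaustive over copy assignments and capped at stoichiometry 8, which is
exact, deterministic, and far above the fixtures' range. `diff` reports
positionwise residue edits (not a minimal edit script), nick/crosslink set
changes, and attribute changes, and is empty exactly when `is_equal` holds.

## Synthetic corpora

The corpus generator is the package's test surface for the grammar and the
validator. Clean records draw sequence length (default 5–30), modified
residues (p = 0.10 per position), inline definitions, nicks (p = 0.10),
disulfide crosslinks between planted cysteines (p = 0.30), circularity
(p = 0.10), terminal caps, and extra-mass/charge attributes from a seeded
RNG; records are a pure function of the generator's parameter set, seed
included. Defect records
are constructed per rule (V1–V9, each guaranteed to trip at least its
intended rule) or by corrupting a clean string (five syntax-defect classes).
The generator emulates the combinatorics of real descriptions, not the
statistics of real proteomes: residue usage is uniform, modifications are
drawn from the small packaged set, and crosslinks are disulfides only, so a
passing suite demonstrates correctness of parsing/validation/assembly over
the representation space, not biological realism of any particular corpus.

The acceptance script regenerates all corpora from a command-line seed at the
sizes above (1000 polymers, 200 complexes, 450 semantic + 100 syntax + 200
clean records, 100 duality and 100 compatibility cases) — sizes chosen so the
whole run completes in seconds while every code path is exercised hundreds of
times.

## Known limitations

The packaged alphabets are curated working sets, not reconstructions of the
full published modification databases; counts of residues are therefore not a
meaningful output. Atom indices follow the stored SMILES of this package's
fixtures and are not guaranteed to coincide with indices assigned by any
particular vendor canonicalizer. Protonation and tautomer states are not
modeled; charges are formal charges. Visualization, 3D/PDB export, and
pathway-format integration are out of scope.
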
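"""Alphabets of residues/caps and the ontology of crosslinks.

An alphabet maps short residue codes (one letter, or multi-character codes
written in braces inside polymer descriptions) to full molecular definitions:
a structure stored as SMILES, the atoms that can bond to the preceding (left)
and following (right) residue, and the atoms displaced when those bonds form.
A residue with no left bond atoms can only start a chain (a 5' cap or an
amino-terminal cap); one with no right bond atoms can only end it.

Crosslink types are defined the same way, except that their atom lists are
interpreted relative to the two residues the crosslink joins.

Alphabets and ontologies are stored as YAML documents; the fixtures packaged
under ``macromol/data`` cover the canonical DNA/RNA/protein residues plus a
curated set of modified residues, caps, and common protein crosslinks
(disulfide, isopeptide, thioester).
"""

from __future__ import annotations

import difflib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from .molgraph import MolecularGraph, atom_at, parse_smiles, MolGraphError, SmilesError


class AlphabetError(ValueError):
    """Schema violation or unresolvable definition in an alphabet/ontology file."""


_ATOM_SPEC_RE = re.compile(r"^([A-Z][a-z]?)(\d+)([+-]\d+)?$")


@dataclass(frozen=True)
class AtomSpec:
    """Coordinate of one atom inside a residue structure.

    ``index`` is the 1-based position of the atom in the stored SMILES order.
    For element ``H`` the index names the heavy atom whose implicit hydrogen
    is meant (implicit hydrogens themselves are not indexed).  ``charge_delta``
    is added to the referenced atom's formal charge when the bond forms.
    """

    element: str
    index: int
    charge_delta: int = 0

    def __post_init__(self):
        if self.index < 1:
            raise AlphabetError(f"atom index must be >= 1, got {self.index}")

    @classmethod
    def from_string(cls, text: str) -> "AtomSpec":
        m = _ATOM_SPEC_RE.match(text.strip())
        if not m:
            raise AlphabetError(
                f"malformed atom reference {text!r}; expected e.g. 'C2', 'H1', 'O3-1'"
            )
        element, index, delta = m.groups()
        return cls(element, int(index), int(delta) if delta else 0)

    def __str__(self) -> str:
        delta = ""
        if self.charge_delta:
            delta = f"{'+' if self.charge_delta > 0 else '-'}{abs(self.charge_delta)}"
        return f"{self.element}{self.index}{delta}"

    def resolve(self, structure: MolecularGraph, require_h: bool = True) -> None:
        """Check that this spec addresses a real atom of ``structure``.

        For element ``H``, the referenced heavy atom must carry at least one
        implicit hydrogen when ``require_h`` (availability under multiple
        bonds is re-checked at validation time).  Raises
        :class:`MolGraphError` on mismatch.
        """
        if self.element == "H":
            heavy = structure.atoms[self.index - 1] if 1 <= self.index <= len(structure) else None
            if heavy is None:
                raise MolGraphError(
                    f"atom index {self.index} out of range 1..{len(structure)}"
                )
            if heavy.element == "H":
                return  # an explicit monatomic hydrogen
            if require_h and heavy.implicit_h < 1:
                raise MolGraphError(
                    f"atom {self.index} ({heavy.element}) has no implicit hydrogen to reference"
                )
        else:
            atom_at(structure, self.element, self.index)


def _parse_atom_specs(values, where: str) -> list[AtomSpec]:
    specs = []
    for value in values or []:
        try:
            specs.append(AtomSpec.from_string(str(value)))
        except AlphabetError as exc:
            raise AlphabetError(f"{where}: {exc}") from exc
    return specs


@dataclass
class Residue:
    """A monomer or cap: structure plus left/right bonding chemistry."""

    code: str
    id: str = ""
    name: str = ""
    structure: MolecularGraph = None
    structure_smiles: str = ""
    l_bond_atoms: list[AtomSpec] = field(default_factory=list)
    r_bond_atoms: list[AtomSpec] = field(default_factory=list)
    l_displaced_atoms: list[AtomSpec] = field(default_factory=list)
    r_displaced_atoms: list[AtomSpec] = field(default_factory=list)
    base_monomers: list[str] = field(default_factory=list)
    aliases: list[str] = field(default_factory=list)
    xrefs: list[tuple[str, str]] = field(default_factory=list)
    comments: str = ""

    @property
    def is_left_cap(self) -> bool:
        return not self.l_bond_atoms

    @property
    def is_right_cap(self) -> bool:
        return not self.r_bond_atoms

    def resolve_atom_specs(self) -> None:
        """Validate every atom spec against the structure; raises on mismatch."""
        for kind, specs in (
            ("l-bond-atom", self.l_bond_atoms),
            ("r-bond-atom", self.r_bond_atoms),
            ("l-displaced-atom", self.l_displaced_atoms),
            ("r-displaced-atom", self.r_displaced_atoms),
        ):
            for spec in specs:
                try:
                    spec.resolve(self.structure)
                except MolGraphError as exc:
                    raise AlphabetError(
                        f"residue {self.code!r}, {kind} {spec}: {exc}"
                    ) from exc


@dataclass
class CrosslinkType:
    """A named crosslink: atoms bonded and displaced on each side."""

    id: str
    name: str = ""
    l_bond_atoms: list[AtomSpec] = field(default_factory=list)
    r_bond_atoms: list[AtomSpec] = field(default_factory=list)
    l_displaced_atoms: list[AtomSpec] = field(default_factory=list)
    r_displaced_atoms: list[AtomSpec] = field(default_factory=list)
    l_allowed_residues: list[str] | None = None
    r_allowed_residues: list[str] | None = None
    comments: str = ""


@dataclass
class Alphabet:
    id: str
    name: str = ""
    type: str = "protein"  # one of DNA, RNA, protein
    residues: dict[str, Residue] = field(default_factory=dict)

    #: canonical code used for residues without base monomers in exports
    @property
    def unknown_code(self) -> str:
        return "X" if self.type == "protein" else "N"

    def get_residue(self, code: str) -> Residue:
        """Residue for ``code`` (alias-aware); unknown codes raise with suggestions."""
        code = code.strip("{}")
        if code in self.residues:
            return self.residues[code]
        near = difflib.get_close_matches(code, self.residues, n=3, cutoff=0.5)
        hint = f"; nearest codes: {', '.join(near)}" if near else ""
        raise AlphabetError(f"unknown residue code {code!r} in alphabet {self.id!r}{hint}")

    def __contains__(self, code: str) -> bool:
        return code.strip("{}") in self.residues

    def canonical_codes(self) -> list[str]:
        """Single-letter codes of unmodified residues (no base monomers, no cap)."""
        return sorted(
            code
            for code, residue in self.residues.items()
            if len(code) == 1
            and not residue.base_monomers
            and residue.l_bond_atoms
            and residue.r_bond_atoms
            and residue.code == code
        )


@dataclass
class CrosslinkOntology:
    id: str = "crosslinks"
    name: str = ""
    types: dict[str, CrosslinkType] = field(default_factory=dict)

    def get(self, type_id: str) -> CrosslinkType:
        if type_id not in self.types:
            near = difflib.get_close_matches(type_id, self.types, n=3, cutoff=0.5)
            hint = f"; nearest: {', '.join(near)}" if near else ""
            raise AlphabetError(f"unknown crosslink type {type_id!r}{hint}")
        return self.types[type_id]


# ---------------------------------------------------------------------------
# I/O

def _residue_from_mapping(code: str, data: dict) -> Residue:
    if not isinstance(data, dict):
        raise AlphabetError(f"residue {code!r}: expected a mapping")
    smiles = data.get("structure")
    if not smiles:
        raise AlphabetError(f"residue {code!r}: missing 'structure' (SMILES)")
    try:
        structure = parse_smiles(smiles)
    except SmilesError as exc:
        raise AlphabetError(f"residue {code!r}: bad SMILES: {exc}") from exc
    where = f"residue {code!r}"
    residue = Residue(
        code=code,
        id=data.get("id", code),
        name=data.get("name", ""),
        structure=structure,
        structure_smiles=smiles,
        l_bond_atoms=_parse_atom_specs(data.get("l_bond_atoms"), where),
        r_bond_atoms=_parse_atom_specs(data.get("r_bond_atoms"), where),
        l_displaced_atoms=_parse_atom_specs(data.get("l_displaced_atoms"), where),
        r_displaced_atoms=_parse_atom_specs(data.get("r_displaced_atoms"), where),
        base_monomers=[str(b) for b in data.get("base_monomers", [])],
        aliases=[str(a) for a in data.get("aliases", [])],
        xrefs=[(str(db), str(acc)) for db, acc in (data.get("xrefs") or [])],
        comments=data.get("comments", ""),
    )
    residue.resolve_atom_specs()
    return residue


def load_alphabet(source: str | Path) -> Alphabet:
    """Load an alphabet from a YAML file path or a YAML string."""
    data = _load_yaml(source)
    for key in ("id", "type", "residues"):
        if key not in data:
            raise AlphabetError(f"alphabet file missing required key {key!r}")
    if data["type"] not in ("DNA", "RNA", "protein"):
        raise AlphabetError(f"alphabet type must be DNA, RNA, or protein, got {data['type']!r}")
    alphabet = Alphabet(id=data["id"], name=data.get("name", ""), type=data["type"])
    for code, rdata in data["residues"].items():
        code = str(code)
        residue = _residue_from_mapping(code, rdata)
        if code in alphabet.residues:
            raise AlphabetError(f"duplicate residue code {code!r}")
        alphabet.residues[code] = residue
        for alias in residue.aliases:
            if alias in alphabet.residues:
                raise AlphabetError(
                    f"alias {alias!r} of residue {code!r} collides with an existing code"
                )
            alphabet.residues[alias] = residue
    for code, residue in alphabet.residues.items():
        for base in residue.base_monomers:
            if base not in alphabet.residues:
                raise AlphabetError(
                    f"residue {code!r}: base monomer {base!r} not in alphabet"
                )
    return alphabet


def _residue_to_mapping(residue: Residue) -> dict:
    out: dict = {
        "id": residue.id,
        "name": residue.name,
        "structure": residue.structure_smiles,
    }
    for key, specs in (
        ("l_bond_atoms", residue.l_bond_atoms),
        ("r_bond_atoms", residue.r_bond_atoms),
        ("l_displaced_atoms", residue.l_displaced_atoms),
        ("r_displaced_atoms", residue.r_displaced_atoms),
    ):
        if specs:
            out[key] = [str(s) for s in specs]
    if residue.base_monomers:
        out["base_monomers"] = list(residue.base_monomers)
    if residue.aliases:
        out["aliases"] = list(residue.aliases)
    if residue.xrefs:
        out["xrefs"] = [[db, acc] for db, acc in residue.xrefs]
    if residue.comments:
        out["comments"] = residue.comments
    return out


def save_alphabet(alphabet: Alphabet, path: str | Path) -> None:
    """Write an alphabet back to YAML; ``load_alphabet`` round-trips it."""
    residues = {}
    for code, residue in alphabet.residues.items():
        if code != residue.code:
            continue  # alias entry; serialized on the primary record
        residues[code] = _residue_to_mapping(residue)
    doc = {
        "id": alphabet.id,
        "name": alphabet.name,
        "type": alphabet.type,
        "residues": residues,
    }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def load_ontology(source: str | Path) -> CrosslinkOntology:
    """Load a crosslink ontology from a YAML file path or YAML string."""
    data = _load_yaml(source)
    if "types" not in data:
        raise AlphabetError("ontology file missing required key 'types'")
    ontology = CrosslinkOntology(id=data.get("id", "crosslinks"), name=data.get("name", ""))
    for type_id, tdata in data["types"].items():
        type_id = str(type_id)
        if type_id in ontology.types:
            raise AlphabetError(f"duplicate crosslink id {type_id!r}")
        where = f"crosslink {type_id!r}"
        ontology.types[type_id] = CrosslinkType(
            id=type_id,
            name=tdata.get("name", ""),
            l_bond_atoms=_parse_atom_specs(tdata.get("l_bond_atoms"), where),
            r_bond_atoms=_parse_atom_specs(tdata.get("r_bond_atoms"), where),
            l_displaced_atoms=_parse_atom_specs(tdata.get("l_displaced_atoms"), where),
            r_displaced_atoms=_parse_atom_specs(tdata.get("r_displaced_atoms"), where),
            l_allowed_residues=tdata.get("l_allowed_residues"),
            r_allowed_residues=tdata.get("r_allowed_residues"),
            comments=tdata.get("comments", ""),
        )
    return ontology


def save_ontology(ontology: CrosslinkOntology, path: str | Path) -> None:
    types = {}
    for type_id, xl in ontology.types.items():
        out: dict = {"name": xl.name}
        for key, specs in (
            ("l_bond_atoms", xl.l_bond_atoms),
            ("r_bond_atoms", xl.r_bond_atoms),
            ("l_displaced_atoms", xl.l_displaced_atoms),
            ("r_displaced_atoms", xl.r_displaced_atoms),
        ):
            if specs:
                out[key] = [str(s) for s in specs]
        if xl.l_allowed_residues is not None:
            out["l_allowed_residues"] = list(xl.l_allowed_residues)
        if xl.r_allowed_residues is not None:
            out["r_allowed_residues"] = list(xl.r_allowed_residues)
        if xl.comments:
            out["comments"] = xl.comments
        types[type_id] = out
    doc = {"id": ontology.id, "name": ontology.name, "types": types}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _load_yaml(source: str | Path) -> dict:
    if isinstance(source, Path) or (
        isinstance(source, str) and "\n" not in source and Path(source).exists()
    ):
        text = Path(source).read_text()
    else:
        text = str(source)
    try:
        data = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise AlphabetError(f"malformed YAML: {exc}") from exc
    if not isinstance(data, dict):
        raise AlphabetError("expected a YAML mapping at the top level")
    return data


_FIXTURES = {"dna": "dna.yml", "rna": "rna.yml", "protein": "protein.yml"}


def packaged_alphabet(name: str) -> Alphabet:
    """Load one of the packaged fixture alphabets: 'dna', 'rna', or 'protein'."""
    if name not in _FIXTURES:
        raise AlphabetError(f"no packaged alphabet {name!r}; choose from {sorted(_FIXTURES)}")
    text = resources.files("macromol.data").joinpath(_FIXTURES[name]).read_text()
    return load_alphabet(text)


def packaged_ontology() -> CrosslinkOntology:
    """Load the packaged crosslink ontology fixture."""
    text = resources.files("macromol.data").joinpath("crosslinks.yml").read_text()
    return load_ontology(text)
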
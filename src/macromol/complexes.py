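"""Grammar and data model for complex descriptions.

A complex is a bag of subunits with stoichiometries plus inter-subunit
crosslinks::

    2 * pep | x-link: [type: disulfide | l: pep(1)-2 | r: pep(2)-2]

Subunit structures (polymers or small molecules) are supplied out of band as a
mapping from subunit id to a :class:`~macromol.polymer.Polymer` or
:class:`~macromol.molgraph.MolecularGraph`; a crosslink slot ``pep(1)-2``
addresses residue 2 of copy 1 of subunit ``pep``.  Explicit-atom crosslinks
extend the slot with an atom coordinate, e.g. ``l-bond-atom: pep(1)-2S7``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .alphabet import AlphabetError, AtomSpec, CrosslinkOntology
from .molgraph import MolecularGraph
from .polymer import Cursor, GrammarError, Polymer, _FIELD_NAME


@dataclass
class Subunit:
    id: str
    stoichiometry: int
    structure: Polymer | MolecularGraph | None = None


@dataclass(frozen=True)
class SubunitResidueRef:
    """(subunit id, copy number, residue position) naming one crosslink slot."""

    subunit_id: str
    copy: int
    residue: int

    def __str__(self) -> str:
        return f"{self.subunit_id}({self.copy})-{self.residue}"


@dataclass(frozen=True)
class SubunitAtomRef:
    """A residue slot extended with an atom coordinate."""

    slot: SubunitResidueRef
    atom: AtomSpec

    def __str__(self) -> str:
        return f"{self.slot}{self.atom}"


@dataclass
class ComplexCrosslink:
    """Inter-subunit crosslink: typed (ontology id + two slots) or explicit."""

    type_id: str | None = None
    l_slot: SubunitResidueRef | None = None
    r_slot: SubunitResidueRef | None = None
    l_bond_atoms: list[SubunitAtomRef] = field(default_factory=list)
    r_bond_atoms: list[SubunitAtomRef] = field(default_factory=list)
    l_displaced_atoms: list[SubunitAtomRef] = field(default_factory=list)
    r_displaced_atoms: list[SubunitAtomRef] = field(default_factory=list)
    comments: str = ""

    @property
    def is_typed(self) -> bool:
        return self.type_id is not None

    def slots(self) -> tuple[SubunitResidueRef, SubunitResidueRef]:
        if self.is_typed:
            return self.l_slot, self.r_slot
        return self.l_bond_atoms[0].slot, self.r_bond_atoms[0].slot


@dataclass
class Complex:
    subunits: list[Subunit] = field(default_factory=list)
    crosslinks: list[ComplexCrosslink] = field(default_factory=list)

    def subunit(self, subunit_id: str) -> Subunit:
        for su in self.subunits:
            if su.id == subunit_id:
                return su
        raise GrammarError(f"unknown subunit id {subunit_id!r}")

    def attach(self, structures: dict[str, Polymer | MolecularGraph]) -> None:
        for su in self.subunits:
            if su.id in structures:
                su.structure = structures[su.id]


_SLOT_RE = re.compile(r"([A-Za-z_][A-Za-z0-9_.-]*)\s*\(\s*(\d+)\s*\)\s*-\s*(\d+)")
_ATOM_TAIL_RE = re.compile(r"([A-Z][a-z]?)(\d+)([+-]\d+)?")


def _parse_slot(cur: Cursor, cx: Complex) -> SubunitResidueRef:
    cur.skip_ws()
    m = _SLOT_RE.match(cur.text, cur.pos)
    if not m:
        raise GrammarError(
            "malformed crosslink slot", cur.text, cur.pos,
            ["<subunit id>(<copy>)-<residue position>, e.g. pep(1)-2"],
        )
    cur.pos = m.end()
    subunit_id, copy, residue = m.group(1), int(m.group(2)), int(m.group(3))
    su = None
    for s in cx.subunits:
        if s.id == subunit_id:
            su = s
            break
    if su is None:
        raise GrammarError(
            f"crosslink names unknown subunit {subunit_id!r}", cur.text, m.start(1)
        )
    if not (1 <= copy <= su.stoichiometry):
        raise GrammarError(
            f"copy index {copy} of subunit {subunit_id!r} exceeds stoichiometry "
            f"{su.stoichiometry}", cur.text, m.start(1),
        )
    return SubunitResidueRef(subunit_id, copy, residue)


def _parse_complex_crosslink(cur: Cursor, cx: Complex,
                             ontology: CrosslinkOntology | None) -> ComplexCrosslink:
    cur.expect("[", ["'[' after x-link:"])
    xl = ComplexCrosslink()
    start = cur.pos
    while True:
        name = cur.match(_FIELD_NAME, "crosslink field name")
        cur.expect(":", ["':' after field name"])
        if name == "type":
            xl.type_id = cur.match(r"[A-Za-z0-9_.-]+", "crosslink type id")
            if ontology is not None:
                try:
                    ontology.get(xl.type_id)
                except AlphabetError as exc:
                    raise GrammarError(str(exc), cur.text, start) from exc
        elif name == "l":
            xl.l_slot = _parse_slot(cur, cx)
        elif name == "r":
            xl.r_slot = _parse_slot(cur, cx)
        elif name in ("l-bond-atom", "r-bond-atom", "l-displaced-atom", "r-displaced-atom"):
            slot = _parse_slot(cur, cx)
            m = _ATOM_TAIL_RE.match(cur.text, cur.pos)
            if not m:
                raise GrammarError(
                    "crosslink atom reference needs an atom coordinate",
                    cur.text, cur.pos, ["e.g. pep(1)-2S7"],
                )
            cur.pos = m.end()
            element, index, delta = m.groups()
            ref = SubunitAtomRef(
                slot, AtomSpec(element, int(index), int(delta) if delta else 0)
            )
            getattr(xl, name.replace("-atom", "_atoms").replace("-", "_")).append(ref)
        elif name == "comments":
            xl.comments = cur.quoted()
        else:
            raise GrammarError(
                f"unknown crosslink field {name!r}", cur.text, start,
                ["type", "l", "r", "l-bond-atom", "r-bond-atom",
                 "l-displaced-atom", "r-displaced-atom", "comments"],
            )
        if cur.take("]"):
            break
        cur.expect("|", ["'|'", "']'"])
    if xl.is_typed:
        if xl.l_slot is None or xl.r_slot is None:
            raise GrammarError("typed crosslink needs both l and r slots", cur.text, start)
    elif not xl.l_bond_atoms or not xl.r_bond_atoms:
        raise GrammarError(
            "crosslink needs either a type or explicit l/r bond atoms", cur.text, start
        )
    lslot, rslot = xl.slots()
    if (lslot.subunit_id, lslot.copy, lslot.residue) == (rslot.subunit_id, rslot.copy, rslot.residue):
        raise GrammarError(
            f"crosslink endpoints refer to the same residue {lslot}", cur.text, start
        )
    return xl


def parse_complex(
    text: str,
    subunit_structures: dict[str, Polymer | MolecularGraph] | None = None,
    ontology: CrosslinkOntology | None = None,
) -> Complex:
    """Parse a complex description; attach structures from ``subunit_structures``."""
    if not text or not text.strip():
        raise GrammarError("empty complex description", text or "", 0)
    cur = Cursor(text)
    cx = Complex()
    while True:
        stoich = int(cur.match(r"\d+", "stoichiometry integer"))
        cur.expect("*", ["'*' between stoichiometry and subunit id"])
        sid = cur.match(r"[A-Za-z_][A-Za-z0-9_.-]*", "subunit id")
        if stoich < 1:
            raise GrammarError(f"stoichiometry of {sid!r} must be >= 1", text, cur.pos)
        if any(su.id == sid for su in cx.subunits):
            raise GrammarError(f"duplicate subunit id {sid!r}", text, cur.pos)
        cx.subunits.append(Subunit(sid, stoich))
        if not cur.take("+"):
            break
    while cur.take("|"):
        start = cur.pos
        name = cur.match(_FIELD_NAME, "attribute name")
        cur.expect(":", ["':' after attribute name"])
        if name == "x-link":
            cx.crosslinks.append(_parse_complex_crosslink(cur, cx, ontology))
        else:
            raise GrammarError(
                f"unknown attribute {name!r}", text, start, ["x-link"]
            )
    if not cur.eof():
        raise GrammarError(f"trailing input {cur.text[cur.pos:cur.pos + 10]!r}", text, cur.pos)
    if subunit_structures:
        cx.attach(subunit_structures)
    return cx


def serialize_complex(cx: Complex) -> str:
    """Deterministic text form; ``parse_complex`` round-trips it."""
    parts = [f"{su.stoichiometry} * {su.id}" for su in cx.subunits]
    text = " + ".join(parts)
    for xl in cx.crosslinks:
        fields = []
        if xl.is_typed:
            fields.append(f"type: {xl.type_id}")
            fields.append(f"l: {xl.l_slot}")
            fields.append(f"r: {xl.r_slot}")
        else:
            for fname, refs in (
                ("l-bond-atom", xl.l_bond_atoms),
                ("l-displaced-atom", xl.l_displaced_atoms),
                ("r-bond-atom", xl.r_bond_atoms),
                ("r-displaced-atom", xl.r_displaced_atoms),
            ):
                fields.extend(f"{fname}: {ref}" for ref in refs)
        if xl.comments:
            fields.append(f'comments: "{xl.comments}"')
        text += " | x-link: [" + " | ".join(fields) + "]"
    return text
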
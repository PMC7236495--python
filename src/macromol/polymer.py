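"""Grammar and data model for polymer descriptions.

A polymer is written as a sequence of residue units followed by optional
attributes separated by ``|``:

* a single letter is an alphabet code (``A``), a multi-character code is
  written in braces (``{SEP}``),
* an inline residue definition is written in square brackets
  (``[id: res | structure: "NCC(O)=O" | l-bond-atom: N1 | ...]``),
* ``:`` between units is a nick (no backbone bond there),
* attributes: ``circular``, ``x-link: [type: disulfide | l: 2 | r: 6]`` (or
  explicit atoms, e.g. ``l-bond-atom: 2S7``), ``extra: [mass: 79.97 |
  charge: -2]``, and ``comments: "..."``.

Whitespace is insignificant outside quotes and the grammar is case-sensitive.
Any plain IUPAC/IUBMB string over an alphabet's canonical one-letter codes is
a valid polymer description, so the grammar is backward compatible with
ordinary sequence notation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .alphabet import Alphabet, AlphabetError, AtomSpec, CrosslinkOntology, Residue
from .molgraph import SmilesError, parse_smiles


class GrammarError(ValueError):
    """Syntax or resolution error in a polymer/complex description."""

    def __init__(self, message: str, text: str | None = None, pos: int | None = None,
                 expected: list[str] | None = None):
        self.pos = pos
        self.expected = expected or []
        if text is not None and pos is not None:
            line = text.count("\n", 0, pos) + 1
            col = pos - (text.rfind("\n", 0, pos) + 1) + 1
            message = f"{message} (line {line}, column {col})"
        if self.expected:
            message = f"{message}; expected one of: {', '.join(self.expected)}"
        super().__init__(message)


@dataclass
class ResidueOccurrence:
    """One residue at a 1-based position of the sequence.

    ``position_range`` records uncertainty about the true location: the
    residue is written at a concrete anchor position but may lie anywhere in
    ``[lo, hi]``.  ``code`` is the alphabet code the occurrence was written
    with, or ``None`` for an inline-defined residue.
    """

    residue: Residue
    position: int
    code: str | None = None
    position_range: tuple[int, int] | None = None
    comments: str = ""

    @property
    def is_inline(self) -> bool:
        return self.code is None


@dataclass
class Crosslink:
    """Covalent bond between two non-adjacent residues.

    Either ``type_id`` names an ontology entry and ``l_residue``/``r_residue``
    give the residue positions, or the four explicit atom lists give
    (residue position, atom spec) pairs.
    """

    type_id: str | None = None
    l_residue: int | None = None
    r_residue: int | None = None
    l_bond_atoms: list[tuple[int, AtomSpec]] = field(default_factory=list)
    r_bond_atoms: list[tuple[int, AtomSpec]] = field(default_factory=list)
    l_displaced_atoms: list[tuple[int, AtomSpec]] = field(default_factory=list)
    r_displaced_atoms: list[tuple[int, AtomSpec]] = field(default_factory=list)
    comments: str = ""

    @property
    def is_typed(self) -> bool:
        return self.type_id is not None

    def positions(self) -> tuple[int, int]:
        if self.is_typed:
            return self.l_residue, self.r_residue
        lpos = self.l_bond_atoms[0][0] if self.l_bond_atoms else 0
        rpos = self.r_bond_atoms[0][0] if self.r_bond_atoms else 0
        return lpos, rpos


@dataclass
class Polymer:
    """A polymer: residues, nicks, crosslinks, circularity, and uncertainty."""

    alphabet: Alphabet
    sequence: list[ResidueOccurrence] = field(default_factory=list)
    nicks: set[int] = field(default_factory=set)
    crosslinks: list[Crosslink] = field(default_factory=list)
    circular: bool = False
    extra_mass: float | None = None
    extra_charge: int | None = None
    comments: str = ""

    def __post_init__(self):
        n = len(self.sequence)
        if self.circular and n < 2:
            raise GrammarError(f"circular polymer must have >= 2 residues, got {n}")
        limit = n if self.circular else n - 1
        for i in self.nicks:
            if not (1 <= i <= limit):
                raise GrammarError(
                    f"nick position {i} out of range 1..{limit}"
                    + ("" if self.circular else " (position n requires circularity)")
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def residue_at(self, i: int) -> ResidueOccurrence:
        if not (1 <= i <= len(self.sequence)):
            raise GrammarError(f"residue position {i} out of range 1..{len(self.sequence)}")
        return self.sequence[i - 1]

    def backbone_pairs(self) -> list[tuple[int, int]]:
        """(i, j) residue pairs joined by a backbone bond, nicks excluded."""
        pairs = [
            (i, i + 1)
            for i in range(1, len(self.sequence))
            if i not in self.nicks
        ]
        if self.circular and len(self.sequence) not in self.nicks:
            pairs.append((len(self.sequence), 1))
        return pairs


def length(p: Polymer) -> int:
    return len(p)


def residue_at(p: Polymer, i: int) -> ResidueOccurrence:
    return p.residue_at(i)


# ---------------------------------------------------------------------------
# tokenizer helpers shared with the complex grammar

class Cursor:
    """Scanning cursor over a description; skips whitespace outside quotes."""

    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def eof(self) -> bool:
        self.skip_ws()
        return self.pos >= len(self.text)

    def peek(self) -> str:
        self.skip_ws()
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def take(self, token: str) -> bool:
        self.skip_ws()
        if self.text.startswith(token, self.pos):
            self.pos += len(token)
            return True
        return False

    def expect(self, token: str, expected: list[str] | None = None) -> None:
        if not self.take(token):
            raise GrammarError(
                f"unexpected input {self.text[self.pos:self.pos + 10]!r}",
                self.text, self.pos, expected or [repr(token)],
            )

    def match(self, pattern: str, expected: str) -> str:
        self.skip_ws()
        m = re.compile(pattern).match(self.text, self.pos)
        if not m:
            raise GrammarError(
                f"unexpected input {self.text[self.pos:self.pos + 10]!r}",
                self.text, self.pos, [expected],
            )
        self.pos = m.end()
        return m.group(0)

    def quoted(self) -> str:
        self.skip_ws()
        if self.pos >= len(self.text) or self.text[self.pos] != '"':
            raise GrammarError("expected opening quote", self.text, self.pos, ['"'])
        end = self.text.find('"', self.pos + 1)
        if end < 0:
            raise GrammarError("unterminated quoted string", self.text, self.pos)
        value = self.text[self.pos + 1 : end]
        self.pos = end + 1
        return value


_FIELD_NAME = r"[A-Za-z][A-Za-z0-9-]*"
_XL_ATOM_RE = re.compile(r"(\d+)([A-Z][a-z]?)(\d+)([+-]\d+)?")


def _parse_inline_residue(cur: Cursor) -> tuple[Residue, tuple[int, int] | None, str]:
    """Parse the body of an inline residue definition after ``[``."""
    data: dict = {"l_bond_atoms": [], "r_bond_atoms": [],
                  "l_displaced_atoms": [], "r_displaced_atoms": [],
                  "base_monomers": []}
    rid = ""
    smiles = None
    position_range = None
    comments = ""
    start = cur.pos
    while True:
        name = cur.match(_FIELD_NAME, "field name")
        cur.expect(":", ["':' after field name"])
        if name == "id":
            rid = cur.match(r"[A-Za-z0-9_.-]+", "identifier")
        elif name == "structure":
            smiles = cur.quoted()
        elif name in ("l-bond-atom", "r-bond-atom", "l-displaced-atom", "r-displaced-atom"):
            value = cur.match(r"[A-Z][a-z]?\d+([+-]\d+)?", "atom reference like C2 or O3-1")
            try:
                spec = AtomSpec.from_string(value)
            except AlphabetError as exc:
                raise GrammarError(str(exc), cur.text, cur.pos) from exc
            data[name.replace("-atom", "_atoms").replace("-", "_")].append(spec)
        elif name == "base-monomer":
            data["base_monomers"].append(cur.match(r"[A-Za-z0-9]+", "residue code"))
        elif name == "position":
            value = cur.match(r"\d+\s*-\s*\d+", "position range like 3-8")
            lo, hi = (int(x) for x in value.split("-"))
            position_range = (lo, hi)
        elif name == "comments":
            comments = cur.quoted()
        else:
            raise GrammarError(
                f"unknown inline residue field {name!r}", cur.text, start,
                ["id", "structure", "l-bond-atom", "r-bond-atom", "l-displaced-atom",
                 "r-displaced-atom", "base-monomer", "position", "comments"],
            )
        if cur.take("]"):
            break
        cur.expect("|", ["'|'", "']'"])
    if smiles is None:
        raise GrammarError("inline residue needs a structure field", cur.text, start)
    try:
        structure = parse_smiles(smiles)
    except SmilesError as exc:
        raise GrammarError(f"inline residue SMILES: {exc}", cur.text, start) from exc
    residue = Residue(
        code=None, id=rid, structure=structure, structure_smiles=smiles,
        comments=comments, **data,
    )
    return residue, position_range, comments


def _parse_xl_atom(cur: Cursor) -> tuple[int, AtomSpec]:
    cur.skip_ws()
    m = _XL_ATOM_RE.match(cur.text, cur.pos)
    if not m:
        raise GrammarError(
            "malformed crosslink atom reference", cur.text, cur.pos,
            ["<position><element><atom index>[+n|-n], e.g. 2S7"],
        )
    cur.pos = m.end()
    pos, element, index, delta = m.groups()
    return int(pos), AtomSpec(element, int(index), int(delta) if delta else 0)


def _parse_crosslink(cur: Cursor, ontology: CrosslinkOntology | None) -> Crosslink:
    cur.expect("[", ["'[' after x-link:"])
    xl = Crosslink()
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
            xl.l_residue = int(cur.match(r"\d+", "residue position"))
        elif name == "r":
            xl.r_residue = int(cur.match(r"\d+", "residue position"))
        elif name in ("l-bond-atom", "r-bond-atom", "l-displaced-atom", "r-displaced-atom"):
            pair = _parse_xl_atom(cur)
            getattr(xl, name.replace("-atom", "_atoms").replace("-", "_")).append(pair)
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
        if xl.l_residue is None or xl.r_residue is None:
            raise GrammarError("typed crosslink needs both l and r positions", cur.text, start)
        if xl.l_residue == xl.r_residue:
            raise GrammarError(
                f"crosslink l and r refer to the same residue {xl.l_residue}",
                cur.text, start,
            )
    else:
        if not xl.l_bond_atoms or not xl.r_bond_atoms:
            raise GrammarError(
                "crosslink needs either a type or explicit l/r bond atoms",
                cur.text, start,
            )
        lpos, rpos = xl.positions()
        if lpos == rpos:
            raise GrammarError(
                f"crosslink l and r refer to the same residue {lpos}", cur.text, start
            )
    return xl


def parse_polymer(
    text: str,
    alphabet: Alphabet,
    ontology: CrosslinkOntology | None = None,
) -> Polymer:
    """Parse a polymer description against ``alphabet`` (and ``ontology`` for
    typed crosslinks).  Raises :class:`GrammarError` with location on bad input."""
    if not text or not text.strip():
        raise GrammarError("empty polymer description", text or "", 0)
    cur = Cursor(text)
    sequence: list[ResidueOccurrence] = []
    nicks: set[int] = set()
    circular = False
    crosslinks: list[Crosslink] = []
    extra_mass = None
    extra_charge = None
    comments = ""

    # sequence of units
    while not cur.eof():
        ch = cur.peek()
        if ch == "|":
            break
        if ch == ":":
            cur.take(":")
            if not sequence:
                raise GrammarError("nick before any residue", text, cur.pos - 1)
            if len(sequence) in nicks:
                raise GrammarError(
                    f"duplicate nick after residue {len(sequence)}", text, cur.pos - 1
                )
            nicks.add(len(sequence))
            continue
        if ch == "{":
            start = cur.pos
            cur.take("{")
            code = cur.match(r"[A-Za-z0-9]+", "residue code")
            cur.expect("}", ["'}'"])
            try:
                residue = alphabet.get_residue(code)
            except AlphabetError as exc:
                raise GrammarError(str(exc), text, start) from exc
            sequence.append(
                ResidueOccurrence(residue, position=len(sequence) + 1, code=code)
            )
            continue
        if ch == "[":
            cur.take("[")
            residue, position_range, rcomments = _parse_inline_residue(cur)
            sequence.append(
                ResidueOccurrence(
                    residue, position=len(sequence) + 1, code=None,
                    position_range=position_range, comments=rcomments,
                )
            )
            continue
        if ch.isalpha():
            start = cur.pos
            cur.pos += 1
            try:
                residue = alphabet.get_residue(ch)
            except AlphabetError as exc:
                raise GrammarError(str(exc), text, start) from exc
            sequence.append(
                ResidueOccurrence(residue, position=len(sequence) + 1, code=ch)
            )
            continue
        raise GrammarError(
            f"unexpected character {ch!r} in sequence", text, cur.pos,
            ["residue code", "'{'", "'['", "':'", "'|'"],
        )

    if not sequence:
        raise GrammarError("polymer has no residues", text, 0)

    # attributes
    while cur.take("|"):
        if cur.take("circular"):
            circular = True
            continue
        start = cur.pos
        name = cur.match(_FIELD_NAME, "attribute name")
        cur.expect(":", ["':' after attribute name"])
        if name == "x-link":
            crosslinks.append(_parse_crosslink(cur, ontology))
        elif name == "extra":
            cur.expect("[", ["'['"])
            while True:
                fname = cur.match(_FIELD_NAME, "mass or charge")
                cur.expect(":", ["':'"])
                if fname == "mass":
                    extra_mass = float(cur.match(r"[+-]?\d+(\.\d+)?", "number"))
                elif fname == "charge":
                    extra_charge = int(cur.match(r"[+-]?\d+", "integer"))
                else:
                    raise GrammarError(
                        f"unknown extra field {fname!r}", text, start, ["mass", "charge"]
                    )
                if cur.take("]"):
                    break
                cur.expect("|", ["'|'", "']'"])
        elif name == "comments":
            comments = cur.quoted()
        else:
            raise GrammarError(
                f"unknown attribute {name!r}", text, start,
                ["circular", "x-link", "extra", "comments"],
            )

    if not cur.eof():
        raise GrammarError(
            f"trailing input {cur.text[cur.pos:cur.pos + 10]!r}", text, cur.pos
        )

    n = len(sequence)
    for occ in sequence:
        if occ.position_range is not None:
            lo, hi = occ.position_range
            if not (1 <= lo <= hi <= n) or not (lo <= occ.position <= hi):
                # flagged later by validation rule V9, but nonsensical ranges
                # (inverted, anchored outside) are rejected at parse time
                if lo > hi:
                    raise GrammarError(
                        f"inverted position range {lo}-{hi} at residue {occ.position}", text, 0
                    )
    # crosslink positions are checked against the length by validation (V6)
    return Polymer(
        alphabet=alphabet, sequence=sequence, nicks=nicks, crosslinks=crosslinks,
        circular=circular, extra_mass=extra_mass, extra_charge=extra_charge,
        comments=comments,
    )


# ---------------------------------------------------------------------------
# serialization

def _serialize_inline(occ: ResidueOccurrence) -> str:
    r = occ.residue
    fields = []
    if r.id:
        fields.append(f"id: {r.id}")
    fields.append(f'structure: "{r.structure_smiles}"')
    for fname, specs in (
        ("l-bond-atom", r.l_bond_atoms),
        ("l-displaced-atom", r.l_displaced_atoms),
        ("r-bond-atom", r.r_bond_atoms),
        ("r-displaced-atom", r.r_displaced_atoms),
    ):
        fields.extend(f"{fname}: {spec}" for spec in specs)
    fields.extend(f"base-monomer: {b}" for b in r.base_monomers)
    if occ.position_range is not None:
        fields.append(f"position: {occ.position_range[0]}-{occ.position_range[1]}")
    if occ.comments:
        fields.append(f'comments: "{occ.comments}"')
    return "[" + " | ".join(fields) + "]"


def _serialize_crosslink(xl: Crosslink) -> str:
    fields = []
    if xl.is_typed:
        fields.append(f"type: {xl.type_id}")
        fields.append(f"l: {xl.l_residue}")
        fields.append(f"r: {xl.r_residue}")
    else:
        for fname, pairs in (
            ("l-bond-atom", xl.l_bond_atoms),
            ("l-displaced-atom", xl.l_displaced_atoms),
            ("r-bond-atom", xl.r_bond_atoms),
            ("r-displaced-atom", xl.r_displaced_atoms),
        ):
            fields.extend(f"{fname}: {pos}{spec}" for pos, spec in pairs)
    if xl.comments:
        fields.append(f'comments: "{xl.comments}"')
    return "x-link: [" + " | ".join(fields) + "]"


def serialize_polymer(p: Polymer) -> str:
    """Deterministic text form; ``parse_polymer`` round-trips it."""
    parts = []
    for occ in p.sequence:
        if occ.position > 1 and (occ.position - 1) in p.nicks:
            parts.append(":")
        if occ.is_inline:
            parts.append(_serialize_inline(occ))
        elif len(occ.code) == 1:
            parts.append(occ.code)
        else:
            parts.append("{" + occ.code + "}")
    if p.circular and len(p.sequence) in p.nicks:
        parts.append(":")
    text = "".join(parts)
    attrs = []
    if p.circular:
        attrs.append("circular")
    attrs.extend(_serialize_crosslink(xl) for xl in p.crosslinks)
    if p.extra_mass is not None or p.extra_charge is not None:
        fields = []
        if p.extra_mass is not None:
            fields.append(f"mass: {p.extra_mass:g}")
        if p.extra_charge is not None:
            fields.append(f"charge: {p.extra_charge}")
        attrs.append("extra: [" + " | ".join(fields) + "]")
    if p.comments:
        attrs.append(f'comments: "{p.comments}"')
    for attr in attrs:
        text += " | " + attr
    return text
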
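"""Minimal molecular-graph core built on a SMILES subset.

Residue structures are stored as SMILES strings, and every atom coordinate in
the toolkit refers to the 1-based position of an atom in the order of first
appearance in the stored SMILES of its parent residue.  This module therefore
implements its own deterministic SMILES reader/writer rather than delegating
to a cheminformatics toolkit whose canonical atom ordering is opaque: the atom
order *is* part of the data model.

Supported SMILES subset
-----------------------
* organic-subset atoms (``B C N O P S F Cl Br I`` and aromatic ``b c n o p s``)
* bracket atoms with optional isotope (parsed, ignored with a warning),
  explicit hydrogen count, and formal charge
* bond symbols ``- = # :``, branches, ring closures (``1``..``9`` and
  ``%nn``), and dots for disconnected components

Stereochemistry and isotope semantics are out of scope.  Aromatic (lowercase)
input is kekulized by a perfect matching of double bonds over each aromatic
system; input that cannot be kekulized is rejected.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources


class SmilesError(ValueError):
    """Syntax or chemistry error in a SMILES string, with character offset."""

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class MolGraphError(ValueError):
    """Invalid operation on a molecular graph."""


def _load_atomic_weights() -> dict[str, float]:
    weights = {}
    text = resources.files("macromol.data").joinpath("elements.tsv").read_text()
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        symbol, weight = line.split("\t")
        weights[symbol] = float(weight)
    return weights


#: symbol -> IUPAC standard (average) atomic weight, Da
ATOMIC_WEIGHTS: dict[str, float] = _load_atomic_weights()

#: elements writable without brackets, with their default valence choices
ORGANIC_VALENCES: dict[str, tuple[int, ...]] = {
    "B": (3,),
    "C": (4,),
    "N": (3, 5),
    "O": (2,),
    "P": (3, 5),
    "S": (2, 4, 6),
    "F": (1,),
    "Cl": (1,),
    "Br": (1,),
    "I": (1,),
}

#: tolerance for molecular-weight comparisons, Da
MW_TOLERANCE = 0.01


@dataclass
class Atom:
    """One atom: element, formal charge, and hydrogen bookkeeping.

    ``implicit_h`` counts hydrogens inferred from the default-valence rule for
    organic-subset atoms; it is 0 for atoms written in brackets, whose
    hydrogens are recorded in ``explicit_h`` instead.  ``index`` is the 1-based
    position of the atom in the graph's stored order.
    """

    element: str
    formal_charge: int = 0
    implicit_h: int = 0
    explicit_h: int = 0
    index: int = 0
    # parser-internal flags
    aromatic: bool = field(default=False, repr=False, compare=False)
    bracket: bool = field(default=False, repr=False, compare=False)

    @property
    def total_h(self) -> int:
        return self.implicit_h + self.explicit_h


@dataclass(frozen=True)
class Bond:
    """Covalent bond between atoms ``a`` and ``b`` (1-based indices).

    ``order`` is 1, 2, or 3; aromatic bonds only exist transiently during
    parsing and are kekulized before the graph is returned.
    """

    a: int
    b: int
    order: int = 1

    def key(self) -> frozenset[int]:
        return frozenset((self.a, self.b))


class ElementFormula(dict):
    """Element symbol -> count; renders in Hill order (C, H, then others)."""

    def __str__(self) -> str:
        parts = []
        symbols = sorted(self)
        ordered = [s for s in ("C", "H") if s in self]
        ordered += [s for s in symbols if s not in ("C", "H")]
        for symbol in ordered:
            n = self[symbol]
            if n == 0:
                continue
            parts.append(symbol if n == 1 else f"{symbol}{n}")
        return "".join(parts)

    def __add__(self, other: "ElementFormula") -> "ElementFormula":
        out = ElementFormula(self)
        for symbol, n in other.items():
            out[symbol] = out.get(symbol, 0) + n
        return ElementFormula({s: n for s, n in out.items() if n})

    def __sub__(self, other: "ElementFormula") -> "ElementFormula":
        out = ElementFormula(self)
        for symbol, n in other.items():
            out[symbol] = out.get(symbol, 0) - n
        if any(n < 0 for n in out.values()):
            raise MolGraphError(f"negative element count in {dict(out)}")
        return ElementFormula({s: n for s, n in out.items() if n})

    def __mul__(self, k: int) -> "ElementFormula":
        return ElementFormula({s: n * k for s, n in self.items() if n})

    __rmul__ = __mul__


class MolecularGraph:
    """Atoms in stored order plus a set of bonds."""

    def __init__(self, atoms: list[Atom] | None = None, bonds: list[Bond] | None = None):
        self.atoms: list[Atom] = atoms or []
        self.bonds: list[Bond] = []
        self._bond_keys: set[frozenset[int]] = set()
        for bond in bonds or []:
            self.add_bond(bond.a, bond.b, bond.order)
        self._reindex()

    # -- construction ----------------------------------------------------

    def add_atom(self, atom: Atom) -> Atom:
        atom.index = len(self.atoms) + 1
        self.atoms.append(atom)
        return atom

    def add_bond(self, a: int, b: int, order: int = 1) -> Bond:
        if a == b:
            raise MolGraphError(f"self-bond on atom {a}")
        n = len(self.atoms)
        if not (1 <= a <= n and 1 <= b <= n):
            raise MolGraphError(f"bond ({a}, {b}) outside atom range 1..{n}")
        key = frozenset((a, b))
        if key in self._bond_keys:
            raise MolGraphError(f"duplicate bond between atoms {a} and {b}")
        bond = Bond(a, b, order)
        self.bonds.append(bond)
        self._bond_keys.add(key)
        return bond

    def _reindex(self) -> None:
        for i, atom in enumerate(self.atoms, start=1):
            atom.index = i

    def remove_atoms(self, indices: set[int]) -> None:
        """Delete atoms (1-based) and incident bonds; remaining atoms keep order."""
        keep = [a for a in self.atoms if a.index not in indices]
        remap = {}
        for new_index, atom in enumerate(keep, start=1):
            remap[atom.index] = new_index
        bonds = [b for b in self.bonds if b.a not in indices and b.b not in indices]
        self.atoms = keep
        self._reindex()
        self.bonds = []
        self._bond_keys = set()
        for b in bonds:
            self.add_bond(remap[b.a], remap[b.b], b.order)

    def copy(self) -> "MolecularGraph":
        g = MolecularGraph()
        for atom in self.atoms:
            g.add_atom(
                Atom(
                    element=atom.element,
                    formal_charge=atom.formal_charge,
                    implicit_h=atom.implicit_h,
                    explicit_h=atom.explicit_h,
                    aromatic=atom.aromatic,
                    bracket=atom.bracket,
                )
            )
        for bond in self.bonds:
            g.add_bond(bond.a, bond.b, bond.order)
        return g

    # -- queries ----------------------------------------------------------

    def __len__(self) -> int:
        return len(self.atoms)

    def neighbors(self, index: int) -> list[tuple[int, int]]:
        """(neighbor index, bond order) pairs, ascending by neighbor index."""
        out = []
        for bond in self.bonds:
            if bond.a == index:
                out.append((bond.b, bond.order))
            elif bond.b == index:
                out.append((bond.a, bond.order))
        return sorted(out)

    def bond_order_sum(self, index: int) -> int:
        return sum(order for _, order in self.neighbors(index))


# ---------------------------------------------------------------------------
# parsing

_BRACKET_RE = re.compile(
    r"\[(?P<isotope>\d+)?(?P<symbol>[A-Z][a-z]?|[bcnops])"
    r"(?P<hcount>H\d*)?(?P<charge>\+\+|--|[+-]\d*)?(?::\d+)?\]"
)
_TWO_CHAR_ORGANIC = ("Cl", "Br")
_BOND_ORDERS = {"-": 1, "=": 2, "#": 3, ":": "aromatic"}


def _parse_bracket(text: str, pos: int) -> tuple[Atom, int]:
    m = _BRACKET_RE.match(text, pos)
    if not m:
        raise SmilesError("malformed bracket atom", pos)
    if m.group("isotope"):
        warnings.warn(
            f"isotope label {m.group('isotope')} ignored at character {pos}",
            stacklevel=4,
        )
    symbol = m.group("symbol")
    aromatic = symbol[0].islower()
    element = symbol.capitalize() if aromatic else symbol
    if element not in ATOMIC_WEIGHTS:
        raise SmilesError(f"unknown element {element!r}", pos)
    hcount = 0
    if m.group("hcount"):
        digits = m.group("hcount")[1:]
        hcount = int(digits) if digits else 1
    charge = 0
    raw = m.group("charge")
    if raw:
        if raw in ("++", "--"):
            charge = 2 if raw == "++" else -2
        else:
            sign = 1 if raw[0] == "+" else -1
            charge = sign * (int(raw[1:]) if len(raw) > 1 else 1)
    atom = Atom(
        element=element,
        formal_charge=charge,
        implicit_h=0,
        explicit_h=hcount,
        aromatic=aromatic,
        bracket=True,
    )
    return atom, m.end()


def parse_smiles(text: str) -> MolecularGraph:
    """Parse a SMILES string into a :class:`MolecularGraph`.

    Atoms appear in the graph in their order of first appearance in ``text``;
    implicit hydrogens are filled for organic-subset atoms by the
    default-valence rule after kekulization of any aromatic systems.
    """
    if not text or not text.strip():
        raise SmilesError("empty SMILES string", 0)
    text = text.strip()
    g = MolecularGraph()
    prev: int | None = None  # index of atom awaiting a bond
    pending_order: int | str | None = None
    stack: list[int | None] = []
    ring: dict[int, tuple[int, int | str | None, int]] = {}
    aromatic_bonds: set[frozenset[int]] = set()
    pos = 0
    n = len(text)

    def attach(new_index: int, offset: int) -> None:
        nonlocal prev, pending_order
        if prev is not None:
            order = pending_order
            a1, a2 = g.atoms[prev - 1], g.atoms[new_index - 1]
            if order is None:
                order = "aromatic" if (a1.aromatic and a2.aromatic) else 1
            if order == "aromatic" and not (a1.aromatic and a2.aromatic):
                raise SmilesError("aromatic bond between non-aromatic atoms", offset)
            g.add_bond(prev, new_index, 1 if order == "aromatic" else order)
            if order == "aromatic":
                aromatic_bonds.add(frozenset((prev, new_index)))
        elif pending_order is not None:
            raise SmilesError("bond symbol without preceding atom", offset)
        prev = new_index
        pending_order = None

    while pos < n:
        ch = text[pos]
        if ch == "[":
            atom, end = _parse_bracket(text, pos)
            g.add_atom(atom)
            attach(atom.index, pos)
            pos = end
        elif text[pos : pos + 2] in _TWO_CHAR_ORGANIC:
            atom = g.add_atom(Atom(element=text[pos : pos + 2]))
            attach(atom.index, pos)
            pos += 2
        elif ch in "BCNOPSFI":
            atom = g.add_atom(Atom(element=ch))
            attach(atom.index, pos)
            pos += 1
        elif ch in "bcnops":
            atom = g.add_atom(Atom(element=ch.upper(), aromatic=True))
            attach(atom.index, pos)
            pos += 1
        elif ch in _BOND_ORDERS:
            if pending_order is not None:
                raise SmilesError("two consecutive bond symbols", pos)
            pending_order = _BOND_ORDERS[ch]
            pos += 1
        elif ch == "(":
            if prev is None:
                raise SmilesError("branch with no preceding atom", pos)
            stack.append(prev)
            pos += 1
        elif ch == ")":
            if not stack:
                raise SmilesError("unbalanced parentheses: unexpected ')'", pos)
            if pending_order is not None:
                raise SmilesError("dangling bond symbol before ')'", pos)
            prev = stack.pop()
            pos += 1
        elif ch == ".":
            if pending_order is not None:
                raise SmilesError("bond symbol before '.'", pos)
            prev = None
            pos += 1
        elif ch.isdigit() or ch == "%":
            if ch == "%":
                m = re.match(r"%(\d\d)", text[pos:])
                if not m:
                    raise SmilesError("'%' ring closure needs two digits", pos)
                num = int(m.group(1))
                width = 3
            else:
                num = int(ch)
                width = 1
            if prev is None:
                raise SmilesError("ring closure with no preceding atom", pos)
            if num in ring:
                other, open_order, open_pos = ring.pop(num)
                if other == prev:
                    raise SmilesError(f"ring closure {num} bonds atom to itself", pos)
                order = pending_order if pending_order is not None else open_order
                if (
                    open_order is not None
                    and pending_order is not None
                    and open_order != pending_order
                ):
                    raise SmilesError(f"conflicting bond orders for ring closure {num}", pos)
                a1, a2 = g.atoms[other - 1], g.atoms[prev - 1]
                if order is None:
                    order = "aromatic" if (a1.aromatic and a2.aromatic) else 1
                g.add_bond(other, prev, 1 if order == "aromatic" else order)
                if order == "aromatic":
                    aromatic_bonds.add(frozenset((other, prev)))
                pending_order = None
            else:
                ring[num] = (prev, pending_order, pos)
                pending_order = None
            pos += width
        elif ch.isspace():
            pos += 1
        else:
            raise SmilesError(f"unexpected character {ch!r}", pos)

    if stack:
        raise SmilesError("unbalanced parentheses: missing ')'", n)
    if ring:
        num, (_, _, open_pos) = next(iter(ring.items()))
        raise SmilesError(f"dangling ring closure {num}", open_pos)
    if pending_order is not None:
        raise SmilesError("dangling bond symbol at end of input", n)
    if not g.atoms:
        raise SmilesError("no atoms in SMILES string", 0)

    _kekulize(g, aromatic_bonds)
    _fill_implicit_h(g)
    return g


def _kekulize(g: MolecularGraph, aromatic_bonds: set[frozenset[int]]) -> None:
    """Assign alternating double bonds over the aromatic subgraph.

    Each aromatic atom that requires one double bond (e.g. aromatic carbon,
    pyridine-type nitrogen) must be matched along an aromatic bond; pyrrole-type
    nitrogens and aromatic O/S take no double bond.  Failure to find a perfect
    matching is a kekulization error.
    """
    if not aromatic_bonds:
        if any(a.aromatic for a in g.atoms):
            # isolated lowercase atom with no aromatic bonds, e.g. "c"
            raise SmilesError("aromatic atom outside an aromatic ring")
        return

    def needs_double(atom: Atom) -> bool:
        nbrs = g.neighbors(atom.index)
        if any(order > 1 for _, order in nbrs):
            return False  # already holds an explicit double bond (e.g. c(=O))
        if atom.element == "C":
            return atom.formal_charge == 0
        if atom.element in ("N", "P"):
            sigma = len(nbrs) + atom.explicit_h
            target = 3 + atom.formal_charge
            return target - sigma >= 1
        if atom.element in ("O", "S"):
            return atom.formal_charge > 0
        return False

    need = {a.index for a in g.atoms if a.aromatic and needs_double(a)}
    adjacency: dict[int, list[int]] = {i: [] for i in need}
    for key in aromatic_bonds:
        a, b = tuple(key)
        if a in need and b in need:
            adjacency[a].append(b)
            adjacency[b].append(a)
    for lst in adjacency.values():
        lst.sort()

    matched: dict[int, int] = {}

    order = sorted(need)

    def backtrack(i: int) -> bool:
        while i < len(order) and order[i] in matched:
            i += 1
        if i == len(order):
            return True
        a = order[i]
        for b in adjacency[a]:
            if b not in matched:
                matched[a] = b
                matched[b] = a
                if backtrack(i + 1):
                    return True
                del matched[a], matched[b]
        return False

    if not backtrack(0):
        raise SmilesError("cannot kekulize aromatic system")

    double = {frozenset((a, b)) for a, b in matched.items()}
    new_bonds = []
    for bond in g.bonds:
        if bond.key() in double:
            new_bonds.append(Bond(bond.a, bond.b, 2))
        else:
            new_bonds.append(bond)
    g.bonds = new_bonds
    g._bond_keys = {b.key() for b in new_bonds}


def _fill_implicit_h(g: MolecularGraph) -> None:
    for atom in g.atoms:
        if atom.bracket:
            atom.implicit_h = 0
            continue
        valences = ORGANIC_VALENCES.get(atom.element)
        if valences is None:
            raise SmilesError(f"element {atom.element} requires brackets")
        v = g.bond_order_sum(atom.index)
        for dv in valences:
            if v <= dv:
                atom.implicit_h = dv - v
                break
        else:
            raise SmilesError(
                f"valence overflow on atom {atom.index} ({atom.element}): "
                f"bond order sum {v} exceeds {max(valences)}"
            )


# ---------------------------------------------------------------------------
# writing

def _default_implicit_h(element: str, bond_order_sum: int) -> int | None:
    valences = ORGANIC_VALENCES.get(element)
    if valences is None:
        return None
    for dv in valences:
        if bond_order_sum <= dv:
            return dv - bond_order_sum
    return None


def write_smiles(g: MolecularGraph) -> str:
    """Serialize a graph to SMILES.

    Emission order is depth-first from atom 1 (then the lowest-index atom of
    each remaining component), visiting neighbors in ascending index, so output
    is deterministic.  The output re-parses to a graph isomorphic to the input.
    """
    if not g.atoms:
        raise MolGraphError("cannot write SMILES for an empty graph")

    bond_symbol = {1: "", 2: "=", 3: "#"}

    def atom_token(atom: Atom) -> str:
        v = g.bond_order_sum(atom.index)
        needs_bracket = (
            atom.element not in ORGANIC_VALENCES
            or atom.formal_charge != 0
            or atom.explicit_h > 0
            or _default_implicit_h(atom.element, v) != atom.implicit_h
        )
        if not needs_bracket:
            return atom.element
        h = atom.total_h
        htext = "" if h == 0 else ("H" if h == 1 else f"H{h}")
        c = atom.formal_charge
        if c == 0:
            ctext = ""
        elif c == 1:
            ctext = "+"
        elif c == -1:
            ctext = "-"
        else:
            ctext = f"{'+' if c > 0 else '-'}{abs(c)}"
        return f"[{atom.element}{htext}{ctext}]"

    # single DFS pass builds the spanning tree and classifies back edges;
    # edges are classified when their *second* endpoint is popped, which is
    # correct even when a pushed child is reached first through another path
    visited: set[int] = set()
    order_index: dict[int, int] = {}
    parent_of: dict[int, int | None] = {}
    tree_children: dict[int, list[tuple[int, int]]] = {}
    back_edges: dict[int, list[tuple[int, int]]] = {}
    ring_labels: dict[frozenset[int], int] = {}
    next_label = 1
    components: list[int] = []

    for root_atom in g.atoms:
        if root_atom.index in visited:
            continue
        components.append(root_atom.index)
        stack: list[tuple[int, int | None, int]] = [(root_atom.index, None, 1)]
        while stack:
            node, parent, border = stack.pop()
            if node in visited:
                continue
            visited.add(node)
            order_index[node] = len(order_index)
            parent_of[node] = parent
            tree_children[node] = []
            back_edges.setdefault(node, [])
            if parent is not None:
                tree_children[parent].append((node, border))
            children = []
            for nbr, bo in g.neighbors(node):
                if nbr == parent:
                    continue
                if nbr in visited:
                    key = frozenset((node, nbr))
                    if key not in ring_labels:
                        ring_labels[key] = next_label
                        next_label += 1
                        back_edges[nbr].append((node, bo))
                        back_edges[node].append((nbr, bo))
                else:
                    children.append((nbr, bo))
            for nbr, bo in reversed(children):
                stack.append((nbr, node, bo))

    # emit, iteratively to avoid recursion limits on long chains
    out: list[str] = []
    for ci, start in enumerate(components):
        if ci:
            out.append(".")
        work: list[tuple[str, object]] = [("atom", (start, 1))]
        while work:
            kind, payload = work.pop()
            if kind == "text":
                out.append(payload)  # type: ignore[arg-type]
                continue
            node, border = payload  # type: ignore[misc]
            if parent_of[node] is not None:
                out.append(bond_symbol[border])
            out.append(atom_token(g.atoms[node - 1]))
            for nbr, bo in sorted(back_edges[node], key=lambda t: order_index[t[0]]):
                label = ring_labels[frozenset((node, nbr))]
                if order_index[nbr] > order_index[node]:
                    out.append(bond_symbol[bo])  # symbol on the opening side
                out.append(str(label) if label < 10 else f"%{label:02d}")
            children = tree_children[node]
            frames: list[tuple[str, object]] = []
            for k, (child, bo) in enumerate(children):
                if k < len(children) - 1:
                    frames.append(("text", "("))
                    frames.append(("atom", (child, bo)))
                    frames.append(("text", ")"))
                else:
                    frames.append(("atom", (child, bo)))
            for frame in reversed(frames):
                work.append(frame)
    return "".join(out)


# ---------------------------------------------------------------------------
# properties

def get_formula(g: MolecularGraph) -> ElementFormula:
    """Element counts of the graph, including implicit and bracket hydrogens."""
    formula = ElementFormula()
    for atom in g.atoms:
        formula[atom.element] = formula.get(atom.element, 0) + 1
        h = atom.total_h
        if h:
            formula["H"] = formula.get("H", 0) + h
    return ElementFormula({s: n for s, n in formula.items() if n})


def get_mol_weight(g: MolecularGraph) -> float:
    """Molecular weight in Da from IUPAC standard atomic weights."""
    if not g.atoms:
        raise MolGraphError("molecular weight of an empty graph is undefined")
    return sum(n * ATOMIC_WEIGHTS[s] for s, n in get_formula(g).items())


def get_charge(g: MolecularGraph) -> int:
    """Net formal charge of the graph."""
    return sum(atom.formal_charge for atom in g.atoms)


def atom_at(g: MolecularGraph, element: str, index: int) -> Atom:
    """Atom at 1-based position ``index``, checked against ``element``.

    This is the semantic guard behind every atom coordinate in alphabets,
    crosslinks, and inline residue definitions.
    """
    if not (1 <= index <= len(g.atoms)):
        raise MolGraphError(
            f"atom index {index} out of range 1..{len(g.atoms)}"
        )
    atom = g.atoms[index - 1]
    if atom.element != element:
        raise MolGraphError(
            f"element mismatch at atom {index}: expected {element}, found {atom.element}"
        )
    return atom


def isomorphic_profile(g: MolecularGraph) -> tuple:
    """Order-independent fingerprint used by round-trip tests.

    Two graphs with equal profiles have the same multiset of
    (element, charge, total H, sorted incident bond orders) and the same bond
    multiset; this is the round-trip contract for :func:`write_smiles`.
    """
    atoms = sorted(
        (
            a.element,
            a.formal_charge,
            a.total_h,
            tuple(sorted(order for _, order in g.neighbors(a.index))),
        )
        for a in g.atoms
    )
    bonds = sorted(
        tuple(sorted((g.atoms[b.a - 1].element, g.atoms[b.b - 1].element))) + (b.order,)
        for b in g.bonds
    )
    return (tuple(atoms), tuple(bonds))
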
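"""Semantic validation, molecular assembly, properties, comparison, export.

Validation applies the rule set V1-V9 to a parsed polymer (or complex):

V1  every backbone-bonded adjacent pair is bondable (right atoms on the left
    residue, left atoms on the right residue)
V2  caps sit only where no bond is expected (chain ends or next to nicks)
V3  a circular polymer can close its ring
V4  every atom reference resolves with the right element
V5  every displaced hydrogen exists on its parent atom
V6  crosslink residue positions are within the sequence
V7  ontology crosslinks join residues their definition allows
V8  no atom is consumed by two bonds
V9  uncertainty position ranges are within the sequence

A polymer/complex with an empty error list assembles into a single concrete
molecular graph: residue structures are united, displaced atoms removed
(implicit hydrogens decremented; heavy atoms deleted together with their
hydrogens), and a single bond added per paired bond atom.  Formula, molecular
weight, and charge are computed on that graph; observed-but-uninterpreted
extra mass and charge contribute to weight and charge but cannot contribute
elements to the formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations, product
from pathlib import Path

from Bio.Seq import Seq
from Bio.SeqIO.FastaIO import FastaWriter
from Bio.SeqRecord import SeqRecord

from .alphabet import Alphabet, AtomSpec, CrosslinkOntology, Residue
from .complexes import Complex, ComplexCrosslink, SubunitResidueRef, serialize_complex
from .molgraph import (
    Atom,
    ElementFormula,
    MolecularGraph,
    MolGraphError,
    get_charge as graph_charge,
    get_formula as graph_formula,
    get_mol_weight as graph_mw,
    write_smiles,
)
from .polymer import Crosslink, Polymer, ResidueOccurrence, serialize_polymer


class SemanticsError(ValueError):
    """Operation applied to a molecule that fails validation."""


@dataclass
class Finding:
    rule: str
    location: str
    message: str

    def __str__(self) -> str:
        return f"[{self.rule}] {self.location}: {self.message}"


@dataclass
class ValidationReport:
    errors: list[Finding] = field(default_factory=list)
    warnings: list[Finding] = field(default_factory=list)

    def error(self, rule: str, location: str, message: str) -> None:
        self.errors.append(Finding(rule, location, message))

    def warn(self, rule: str, location: str, message: str) -> None:
        self.warnings.append(Finding(rule, location, message))

    @property
    def ok(self) -> bool:
        return not self.errors

    def rules(self) -> set[str]:
        return {f.rule for f in self.errors}

    def to_text(self) -> str:
        lines = [f"error {f}" for f in self.errors]
        lines += [f"warning {f}" for f in self.warnings]
        return "\n".join(lines) if lines else "ok"

    def to_dict(self) -> dict:
        return {
            "valid": self.ok,
            "errors": [vars(f) for f in self.errors],
            "warnings": [vars(f) for f in self.warnings],
        }


# ---------------------------------------------------------------------------
# crosslink resolution helpers

def _typed_crosslink_atoms(xl_type, side: str):
    """(bond specs, displaced specs) of one side ('l' or 'r') of an ontology entry."""
    return (
        getattr(xl_type, f"{side}_bond_atoms"),
        getattr(xl_type, f"{side}_displaced_atoms"),
    )


def _residue_codes(occ: ResidueOccurrence) -> set[str]:
    codes = set()
    if occ.code:
        codes.add(occ.code)
    if occ.residue.code:
        codes.add(occ.residue.code)
    codes.update(occ.residue.aliases)
    return codes


# ---------------------------------------------------------------------------
# polymer validation

def validate_polymer(p: Polymer, ontology: CrosslinkOntology | None = None) -> ValidationReport:
    """Apply rules V1-V9; findings are reported, never raised."""
    report = ValidationReport()
    n = len(p)

    # V1: bondability of adjacent, non-nicked pairs (circular closure is V3's)
    for i in range(1, n):
        if i in p.nicks:
            continue
        left, right = p.sequence[i - 1], p.sequence[i]
        if not left.residue.r_bond_atoms:
            report.error(
                "V1", f"residues {i}-{i + 1}",
                f"residue {i} has no right bond atoms, cannot bond to residue {i + 1}",
            )
        if not right.residue.l_bond_atoms:
            report.error(
                "V1", f"residues {i}-{i + 1}",
                f"residue {i + 1} has no left bond atoms, cannot bond to residue {i}",
            )

    # V2: cap placement
    for occ in p.sequence:
        i = occ.position
        left_bond_expected = i > 1 and (i - 1) not in p.nicks
        right_bond_expected = i < n and i not in p.nicks
        if occ.residue.is_left_cap and left_bond_expected:
            report.error(
                "V2", f"residue {i}",
                "left cap allowed only at position 1 or immediately right of a nick",
            )
        if occ.residue.is_right_cap and right_bond_expected:
            report.error(
                "V2", f"residue {i}",
                "right cap allowed only at the final position or immediately left of a nick",
            )

    # V3: ring closure of circular polymers
    if p.circular and n >= 2 and n not in p.nicks:
        if not p.sequence[-1].residue.r_bond_atoms:
            report.error("V3", f"residue {n}", "cannot close circle: no right bond atoms")
        if not p.sequence[0].residue.l_bond_atoms:
            report.error("V3", "residue 1", "cannot close circle: no left bond atoms")
        if p.sequence[-1].residue.is_right_cap or p.sequence[0].residue.is_left_cap:
            report.error("V2", f"residue {n if p.sequence[-1].residue.is_right_cap else 1}",
                         "cap in a circular polymer")

    # V4: all residue atom specs resolve (inline residues are unchecked until now)
    for occ in p.sequence:
        for kind, specs in (
            ("l-bond-atom", occ.residue.l_bond_atoms),
            ("r-bond-atom", occ.residue.r_bond_atoms),
            ("l-displaced-atom", occ.residue.l_displaced_atoms),
            ("r-displaced-atom", occ.residue.r_displaced_atoms),
        ):
            for spec in specs:
                try:
                    spec.resolve(occ.residue.structure, require_h=False)
                except MolGraphError as exc:
                    report.error("V4", f"residue {occ.position}", f"{kind} {spec}: {exc}")

    # V6 first for crosslinks so later rules can skip out-of-range ones
    usable_crosslinks: list[tuple[int, Crosslink]] = []
    for k, xl in enumerate(p.crosslinks, start=1):
        positions = set()
        if xl.is_typed:
            positions = {xl.l_residue, xl.r_residue}
        else:
            positions = {pos for pos, _ in (
                xl.l_bond_atoms + xl.r_bond_atoms + xl.l_displaced_atoms + xl.r_displaced_atoms
            )}
        bad = [i for i in sorted(positions) if not (1 <= i <= n)]
        if bad:
            report.error(
                "V6", f"crosslink {k}",
                f"residue position{'s' if len(bad) > 1 else ''} "
                f"{', '.join(map(str, bad))} outside sequence 1..{n}",
            )
            continue
        usable_crosslinks.append((k, xl))
        lpos, rpos = xl.positions()
        lo, hi = min(lpos, rpos), max(lpos, rpos)
        if any(lo <= nick < hi for nick in p.nicks):
            report.warn("V6", f"crosslink {k}", "crosslink spans a nick")

    # V4/V7 on crosslinks
    resolved: list[tuple[int, list, list]] = []  # (k, bond pairs, displaced pairs)
    for k, xl in usable_crosslinks:
        if xl.is_typed:
            if ontology is None:
                report.error("V7", f"crosslink {k}",
                             f"typed crosslink {xl.type_id!r} but no ontology provided")
                continue
            try:
                xl_type = ontology.get(xl.type_id)
            except Exception as exc:
                report.error("V7", f"crosslink {k}", str(exc))
                continue
            sides = []
            ok = True
            for side, pos in (("l", xl.l_residue), ("r", xl.r_residue)):
                occ = p.sequence[pos - 1]
                allowed = getattr(xl_type, f"{side}_allowed_residues")
                if allowed is not None and not (_residue_codes(occ) & set(allowed)):
                    report.error(
                        "V7", f"crosslink {k}",
                        f"{side} residue {pos} ({occ.code or occ.residue.id or 'inline'}) "
                        f"not allowed for {xl.type_id}; allowed: {', '.join(allowed)}",
                    )
                    ok = False
                bond, disp = _typed_crosslink_atoms(xl_type, side)
                for spec in bond + disp:
                    try:
                        spec.resolve(occ.residue.structure)
                    except MolGraphError as exc:
                        report.error("V4", f"crosslink {k}", f"{side} {spec}: {exc}")
                        ok = False
                sides.append((pos, bond, disp))
            if ok:
                (lpos, lbond, ldisp), (rpos, rbond, rdisp) = sides
                bonds = [((lpos, a), (rpos, b)) for a, b in zip(lbond, rbond)]
                disp = [(lpos, s) for s in ldisp] + [(rpos, s) for s in rdisp]
                resolved.append((k, bonds, disp))
        else:
            ok = True
            for kind, pairs in (
                ("l-bond-atom", xl.l_bond_atoms),
                ("r-bond-atom", xl.r_bond_atoms),
                ("l-displaced-atom", xl.l_displaced_atoms),
                ("r-displaced-atom", xl.r_displaced_atoms),
            ):
                for pos, spec in pairs:
                    try:
                        spec.resolve(p.sequence[pos - 1].residue.structure)
                    except MolGraphError as exc:
                        report.error("V4", f"crosslink {k}", f"{kind} {pos}{spec}: {exc}")
                        ok = False
            if ok:
                bonds = list(zip(xl.l_bond_atoms, xl.r_bond_atoms))
                disp = xl.l_displaced_atoms + xl.r_displaced_atoms
                resolved.append((k, bonds, disp))

    # V5/V8: hydrogen availability and double consumption across all bonds
    _check_consumption(report, p, resolved, prefix="")

    # V9: uncertainty ranges
    for occ in p.sequence:
        if occ.position_range is not None:
            lo, hi = occ.position_range
            if not (1 <= lo <= occ.position <= hi <= n):
                report.error(
                    "V9", f"residue {occ.position}",
                    f"position range {lo}-{hi} invalid for anchor {occ.position} "
                    f"in sequence of length {n}",
                )
    return report


def _backbone_bond_jobs(p: Polymer):
    """Per backbone bond: ((i, spec), (j, spec)) bond pairs + displaced atoms."""
    jobs = []
    for i, j in p.backbone_pairs():
        left, right = p.sequence[i - 1].residue, p.sequence[j - 1].residue
        bonds = [
            ((i, a), (j, b)) for a, b in zip(left.r_bond_atoms, right.l_bond_atoms)
        ]
        disp = [(i, s) for s in left.r_displaced_atoms] + [
            (j, s) for s in right.l_displaced_atoms
        ]
        jobs.append((f"backbone {i}-{j}", bonds, disp))
    return jobs


def _check_consumption(report: ValidationReport, p: Polymer, resolved_xl, prefix: str) -> None:
    """Rules V5 and V8 over backbone bonds plus resolved crosslinks."""
    h_demand: dict[tuple[int, int], int] = {}
    heavy_used: dict[tuple[int, int], str] = {}

    def spend(where: str, pos: int, spec: AtomSpec, displaced: bool) -> None:
        key = (pos, spec.index)
        if spec.element == "H":
            h_demand[key] = h_demand.get(key, 0) + 1
            return
        if key in heavy_used:
            report.error(
                "V8", f"{prefix}residue {pos}",
                f"atom {spec} consumed by both {heavy_used[key]} and {where}",
            )
        heavy_used[key] = where

    jobs = _backbone_bond_jobs(p)
    for k, bonds, disp in resolved_xl:
        jobs.append((f"crosslink {k}", bonds, disp))
    for where, bonds, disp in jobs:
        for (lpos, lspec), (rpos, rspec) in bonds:
            spend(where, lpos, lspec, displaced=False)
            spend(where, rpos, rspec, displaced=False)
        for pos, spec in disp:
            spend(where, pos, spec, displaced=True)

    for (pos, index), demand in sorted(h_demand.items()):
        structure = p.sequence[pos - 1].residue.structure
        if not (1 <= index <= len(structure)):
            continue  # already a V4 finding
        atom = structure.atoms[index - 1]
        if atom.implicit_h < demand:
            report.error(
                "V5", f"{prefix}residue {pos}",
                f"{demand} hydrogen(s) displaced from atom {atom.element}{index}, "
                f"but only {atom.implicit_h} implicit hydrogen(s) available",
            )


# ---------------------------------------------------------------------------
# complex validation

def validate_complex(cx: Complex, ontology: CrosslinkOntology | None = None) -> ValidationReport:
    """Per-subunit polymer validation plus complex-scope rules V4-V8."""
    report = ValidationReport()
    if len(cx.subunits) == 1 and cx.subunits[0].stoichiometry == 1 and not cx.crosslinks:
        report.warn("V0", f"subunit {cx.subunits[0].id}",
                    "degenerate complex: a single subunit copy and no crosslinks")
    for su in cx.subunits:
        if su.structure is None:
            report.error("V4", f"subunit {su.id}", "no structure attached")
        elif isinstance(su.structure, Polymer):
            sub = validate_polymer(su.structure, ontology)
            for f in sub.errors:
                report.error(f.rule, f"subunit {su.id}: {f.location}", f.message)
            for f in sub.warnings:
                report.warn(f.rule, f"subunit {su.id}: {f.location}", f.message)
    if not report.ok and any(su.structure is None for su in cx.subunits):
        return report

    # complex-scope crosslinks
    h_demand: dict[tuple, int] = {}
    heavy_used: dict[tuple, str] = {}

    def occ_at(slot: SubunitResidueRef, k: int):
        su = None
        for s in cx.subunits:
            if s.id == slot.subunit_id:
                su = s
        if su is None:
            report.error("V6", f"crosslink {k}", f"unknown subunit {slot.subunit_id!r}")
            return None
        if not (1 <= slot.copy <= su.stoichiometry):
            report.error("V6", f"crosslink {k}",
                         f"copy {slot.copy} exceeds stoichiometry {su.stoichiometry}")
            return None
        if isinstance(su.structure, Polymer):
            if not (1 <= slot.residue <= len(su.structure)):
                report.error(
                    "V6", f"crosslink {k}",
                    f"residue {slot.residue} outside subunit {su.id} (length {len(su.structure)})",
                )
                return None
            return su.structure.sequence[slot.residue - 1]
        if isinstance(su.structure, MolecularGraph):
            if slot.residue != 1:
                report.error("V6", f"crosslink {k}",
                             f"small-molecule subunit {su.id} has a single position 1")
                return None
            return ResidueOccurrence(
                Residue(code=su.id, id=su.id, structure=su.structure,
                        structure_smiles=""), position=1, code=su.id,
            )
        return None

    def spend(where, slot, spec):
        key = (slot.subunit_id, slot.copy, slot.residue, spec.index)
        if spec.element == "H":
            h_demand[key] = h_demand.get(key, 0) + 1
            return None
        if key in heavy_used:
            report.error("V8", f"{slot}", f"atom {spec} consumed by both "
                                          f"{heavy_used[key]} and {where}")
        heavy_used[key] = where
        return None

    for k, xl in enumerate(cx.crosslinks, start=1):
        if xl.is_typed:
            if ontology is None:
                report.error("V7", f"crosslink {k}",
                             f"typed crosslink {xl.type_id!r} but no ontology provided")
                continue
            try:
                xl_type = ontology.get(xl.type_id)
            except Exception as exc:
                report.error("V7", f"crosslink {k}", str(exc))
                continue
            for side, slot in (("l", xl.l_slot), ("r", xl.r_slot)):
                occ = occ_at(slot, k)
                if occ is None:
                    continue
                allowed = getattr(xl_type, f"{side}_allowed_residues")
                if allowed is not None and not (_residue_codes(occ) & set(allowed)):
                    report.error(
                        "V7", f"crosslink {k}",
                        f"{side} residue {slot} not allowed for {xl.type_id}; "
                        f"allowed: {', '.join(allowed)}",
                    )
                bond, disp = _typed_crosslink_atoms(xl_type, side)
                for spec in bond + disp:
                    try:
                        spec.resolve(occ.residue.structure)
                    except MolGraphError as exc:
                        report.error("V4", f"crosslink {k}", f"{side} {spec}: {exc}")
                        continue
                for spec in bond:
                    spend(f"crosslink {k}", slot, spec)
                for spec in disp:
                    spend(f"crosslink {k}", slot, spec)
        else:
            for kind, refs in (
                ("l-bond-atom", xl.l_bond_atoms),
                ("r-bond-atom", xl.r_bond_atoms),
                ("l-displaced-atom", xl.l_displaced_atoms),
                ("r-displaced-atom", xl.r_displaced_atoms),
            ):
                for ref in refs:
                    occ = occ_at(ref.slot, k)
                    if occ is None:
                        continue
                    try:
                        ref.atom.resolve(occ.residue.structure)
                    except MolGraphError as exc:
                        report.error("V4", f"crosslink {k}", f"{kind} {ref}: {exc}")
                        continue
                    spend(f"crosslink {k}", ref.slot, ref.atom)

    # V5 at complex scope: backbone + intra demands are checked per subunit;
    # here only inter-subunit H displacements are totalled against structures
    for (sid, copy, res, index), demand in sorted(h_demand.items()):
        su = cx.subunit(sid)
        structure = (
            su.structure.sequence[res - 1].residue.structure
            if isinstance(su.structure, Polymer)
            else su.structure
        )
        if structure is None or not (1 <= index <= len(structure)):
            continue
        atom = structure.atoms[index - 1]
        if atom.implicit_h < demand:
            report.error(
                "V5", f"{sid}({copy})-{res}",
                f"{demand} hydrogen(s) displaced from atom {atom.element}{index}, "
                f"but only {atom.implicit_h} available",
            )
    return report


# ---------------------------------------------------------------------------
# assembly

class _Assembly:
    """Accumulates residue structures and applies bonds/displacements."""

    def __init__(self):
        self.graph = MolecularGraph()
        self.offsets: dict[tuple, int] = {}  # residue key -> atom index offset
        self.to_delete: set[int] = set()

    def place(self, key: tuple, structure: MolecularGraph) -> None:
        self.offsets[key] = len(self.graph.atoms)
        for atom in structure.atoms:
            self.graph.add_atom(Atom(
                element=atom.element, formal_charge=atom.formal_charge,
                implicit_h=atom.implicit_h, explicit_h=atom.explicit_h,
                aromatic=atom.aromatic, bracket=atom.bracket,
            ))
        offset = self.offsets[key]
        for bond in structure.bonds:
            self.graph.add_bond(bond.a + offset, bond.b + offset, bond.order)

    def global_index(self, key: tuple, spec: AtomSpec) -> int:
        return self.offsets[key] + spec.index

    def bond(self, lkey: tuple, lspec: AtomSpec, rkey: tuple, rspec: AtomSpec) -> None:
        a = self.global_index(lkey, lspec)
        b = self.global_index(rkey, rspec)
        self.graph.add_bond(a, b, 1)
        for idx, spec in ((a, lspec), (b, rspec)):
            if spec.charge_delta:
                self.graph.atoms[idx - 1].formal_charge += spec.charge_delta

    def displace(self, key: tuple, spec: AtomSpec) -> None:
        idx = self.global_index(key, spec)
        atom = self.graph.atoms[idx - 1]
        if spec.element == "H" and atom.element != "H":
            if atom.implicit_h < 1:
                raise SemanticsError(
                    f"no implicit hydrogen left on atom {atom.element}{spec.index}"
                )
            atom.implicit_h -= 1
            if spec.charge_delta:
                atom.formal_charge += spec.charge_delta
        else:
            # deleting the atom also removes its formal charge; a charge delta
            # on a deleted atom would be meaningless and is ignored
            self.to_delete.add(idx)

    def finish(self) -> MolecularGraph:
        if self.to_delete:
            self.graph.remove_atoms(self.to_delete)
        return self.graph


def _assemble_polymer_into(asm: _Assembly, p: Polymer, base_key: tuple,
                           ontology: CrosslinkOntology | None) -> None:
    for occ in p.sequence:
        asm.place(base_key + (occ.position,), occ.residue.structure)
    for where, bonds, disp in _backbone_bond_jobs(p):
        for (lpos, lspec), (rpos, rspec) in bonds:
            asm.bond(base_key + (lpos,), lspec, base_key + (rpos,), rspec)
        for pos, spec in disp:
            asm.displace(base_key + (pos,), spec)
    for xl in p.crosslinks:
        bonds, disp = _crosslink_jobs(p, xl, ontology)
        for (lpos, lspec), (rpos, rspec) in bonds:
            asm.bond(base_key + (lpos,), lspec, base_key + (rpos,), rspec)
        for pos, spec in disp:
            asm.displace(base_key + (pos,), spec)


def _crosslink_jobs(p: Polymer, xl: Crosslink, ontology: CrosslinkOntology | None):
    if xl.is_typed:
        if ontology is None:
            raise SemanticsError(f"crosslink type {xl.type_id!r} needs an ontology")
        xl_type = ontology.get(xl.type_id)
        bonds = [
            ((xl.l_residue, a), (xl.r_residue, b))
            for a, b in zip(xl_type.l_bond_atoms, xl_type.r_bond_atoms)
        ]
        disp = [(xl.l_residue, s) for s in xl_type.l_displaced_atoms] + [
            (xl.r_residue, s) for s in xl_type.r_displaced_atoms
        ]
        return bonds, disp
    bonds = list(zip(xl.l_bond_atoms, xl.r_bond_atoms))
    disp = xl.l_displaced_atoms + xl.r_displaced_atoms
    return bonds, disp


def assemble(molecule: Polymer | Complex,
             ontology: CrosslinkOntology | None = None) -> MolecularGraph:
    """Assemble a validated polymer or complex into one molecular graph.

    Raises :class:`SemanticsError` if validation reports errors; assembly is
    total on validated input.
    """
    if isinstance(molecule, Polymer):
        report = validate_polymer(molecule, ontology)
        if not report.ok:
            raise SemanticsError("cannot assemble invalid polymer:\n" + report.to_text())
        asm = _Assembly()
        _assemble_polymer_into(asm, molecule, (), ontology)
        return asm.finish()

    report = validate_complex(molecule, ontology)
    if not report.ok:
        raise SemanticsError("cannot assemble invalid complex:\n" + report.to_text())
    asm = _Assembly()
    for su in molecule.subunits:
        for copy in range(1, su.stoichiometry + 1):
            if isinstance(su.structure, Polymer):
                _assemble_polymer_into(asm, su.structure, (su.id, copy), ontology)
            else:
                asm.place((su.id, copy, 1), su.structure)
    for xl in molecule.crosslinks:
        if xl.is_typed:
            xl_type = ontology.get(xl.type_id)
            lkey = (xl.l_slot.subunit_id, xl.l_slot.copy, xl.l_slot.residue)
            rkey = (xl.r_slot.subunit_id, xl.r_slot.copy, xl.r_slot.residue)
            for a, b in zip(xl_type.l_bond_atoms, xl_type.r_bond_atoms):
                asm.bond(lkey, a, rkey, b)
            for spec in xl_type.l_displaced_atoms:
                asm.displace(lkey, spec)
            for spec in xl_type.r_displaced_atoms:
                asm.displace(rkey, spec)
        else:
            for lref, rref in zip(xl.l_bond_atoms, xl.r_bond_atoms):
                asm.bond(
                    (lref.slot.subunit_id, lref.slot.copy, lref.slot.residue), lref.atom,
                    (rref.slot.subunit_id, rref.slot.copy, rref.slot.residue), rref.atom,
                )
            for ref in xl.l_displaced_atoms + xl.r_displaced_atoms:
                asm.displace((ref.slot.subunit_id, ref.slot.copy, ref.slot.residue), ref.atom)
    return asm.finish()


# ---------------------------------------------------------------------------
# properties

def get_formula(molecule: Polymer | Complex,
                ontology: CrosslinkOntology | None = None) -> ElementFormula:
    """Chemical formula of the assembled molecule (extra mass carries no elements)."""
    return graph_formula(assemble(molecule, ontology))


def get_mol_weight(molecule: Polymer | Complex,
                   ontology: CrosslinkOntology | None = None) -> float:
    """Molecular weight in Da, including any observed extra mass."""
    mw = graph_mw(assemble(molecule, ontology))
    if isinstance(molecule, Polymer) and molecule.extra_mass:
        mw += molecule.extra_mass
    if isinstance(molecule, Complex):
        for su in molecule.subunits:
            if isinstance(su.structure, Polymer) and su.structure.extra_mass:
                mw += su.stoichiometry * su.structure.extra_mass
    return mw


def get_net_charge(molecule: Polymer | Complex,
                   ontology: CrosslinkOntology | None = None) -> int:
    """Net formal charge, including any observed extra charge."""
    q = graph_charge(assemble(molecule, ontology))
    if isinstance(molecule, Polymer) and molecule.extra_charge:
        q += molecule.extra_charge
    if isinstance(molecule, Complex):
        for su in molecule.subunits:
            if isinstance(su.structure, Polymer) and su.structure.extra_charge:
                q += su.stoichiometry * su.structure.extra_charge
    return q


# ---------------------------------------------------------------------------
# equality and diff

def _match_inline_to_alphabet(occ: ResidueOccurrence, alphabet: Alphabet) -> str | None:
    """Code of an alphabet residue structurally identical to an inline residue."""
    target = (
        write_smiles(occ.residue.structure),
        tuple(map(str, occ.residue.l_bond_atoms)),
        tuple(map(str, occ.residue.r_bond_atoms)),
        tuple(map(str, occ.residue.l_displaced_atoms)),
        tuple(map(str, occ.residue.r_displaced_atoms)),
        tuple(occ.residue.base_monomers),
    )
    for code, residue in alphabet.residues.items():
        if code != residue.code:
            continue
        probe = (
            write_smiles(residue.structure),
            tuple(map(str, residue.l_bond_atoms)),
            tuple(map(str, residue.r_bond_atoms)),
            tuple(map(str, residue.l_displaced_atoms)),
            tuple(map(str, residue.r_displaced_atoms)),
            tuple(residue.base_monomers),
        )
        if probe == target:
            return code
    return None


def _normalized_occurrence_token(occ: ResidueOccurrence, alphabet: Alphabet) -> str:
    if not occ.is_inline:
        return alphabet.get_residue(occ.code).code  # aliases collapse
    code = _match_inline_to_alphabet(occ, alphabet)
    if code is not None and occ.position_range is None and not occ.comments:
        return code
    r = occ.residue
    return "|".join([
        write_smiles(r.structure),
        ",".join(map(str, r.l_bond_atoms)), ",".join(map(str, r.r_bond_atoms)),
        ",".join(map(str, r.l_displaced_atoms)), ",".join(map(str, r.r_displaced_atoms)),
        ",".join(r.base_monomers),
        str(occ.position_range), occ.comments,
    ])


def _normalized_crosslink_token(xl: Crosslink) -> tuple:
    if xl.is_typed:
        return ("typed", xl.type_id, xl.l_residue, xl.r_residue)
    return (
        "explicit",
        tuple((pos, str(s)) for pos, s in xl.l_bond_atoms),
        tuple((pos, str(s)) for pos, s in xl.r_bond_atoms),
        tuple((pos, str(s)) for pos, s in xl.l_displaced_atoms),
        tuple((pos, str(s)) for pos, s in xl.r_displaced_atoms),
    )


def diff(a: Polymer | Complex, b: Polymer | Complex) -> list[dict]:
    """Structured differences; empty exactly when :func:`is_equal` is true."""
    if isinstance(a, Polymer) and isinstance(b, Polymer):
        return _diff_polymers(a, b)
    if isinstance(a, Complex) and isinstance(b, Complex):
        if _complexes_equal(a, b):
            return []
        return _diff_complexes(a, b)
    return [{"kind": "type", "detail": f"{type(a).__name__} vs {type(b).__name__}"}]


def _diff_polymers(a: Polymer, b: Polymer) -> list[dict]:
    out = []
    if len(a) != len(b):
        out.append({"kind": "length", "a": len(a), "b": len(b)})
    for i in range(1, min(len(a), len(b)) + 1):
        ta = _normalized_occurrence_token(a.sequence[i - 1], a.alphabet)
        tb = _normalized_occurrence_token(b.sequence[i - 1], b.alphabet)
        if ta != tb:
            out.append({"kind": "residue", "position": i, "a": ta, "b": tb})
    if a.nicks != b.nicks:
        out.append({"kind": "nicks", "a": sorted(a.nicks), "b": sorted(b.nicks)})
    xa = sorted(map(_normalized_crosslink_token, a.crosslinks))
    xb = sorted(map(_normalized_crosslink_token, b.crosslinks))
    for tok in xa:
        if tok not in xb:
            out.append({"kind": "crosslink-removed", "crosslink": tok})
    for tok in xb:
        if tok not in xa:
            out.append({"kind": "crosslink-added", "crosslink": tok})
    for attr in ("circular", "extra_mass", "extra_charge", "comments"):
        va, vb = getattr(a, attr), getattr(b, attr)
        if va != vb:
            out.append({"kind": "attribute", "attribute": attr, "a": va, "b": vb})
    return out


MAX_PERMUTATION_STOICHIOMETRY = 8


def _complexes_equal(a: Complex, b: Complex) -> bool:
    if sorted((su.id, su.stoichiometry) for su in a.subunits) != sorted(
        (su.id, su.stoichiometry) for su in b.subunits
    ):
        return False
    for su in a.subunits:
        other = b.subunit(su.id)
        if isinstance(su.structure, Polymer) != isinstance(other.structure, Polymer):
            return False
        if isinstance(su.structure, Polymer):
            if _diff_polymers(su.structure, other.structure):
                return False
        elif su.structure is not None and other.structure is not None:
            if write_smiles(su.structure) != write_smiles(other.structure):
                return False
    # crosslink sets up to a permutation of interchangeable subunit copies
    def tokens(cx: Complex, assignment: dict[tuple[str, int], int]):
        toks = []
        for xl in cx.crosslinks:
            def remap(slot: SubunitResidueRef):
                return (slot.subunit_id, assignment.get((slot.subunit_id, slot.copy), slot.copy),
                        slot.residue)
            if xl.is_typed:
                toks.append(("typed", xl.type_id, remap(xl.l_slot), remap(xl.r_slot)))
            else:
                toks.append((
                    "explicit",
                    tuple((remap(r.slot), str(r.atom)) for r in xl.l_bond_atoms),
                    tuple((remap(r.slot), str(r.atom)) for r in xl.r_bond_atoms),
                    tuple((remap(r.slot), str(r.atom)) for r in xl.l_displaced_atoms),
                    tuple((remap(r.slot), str(r.atom)) for r in xl.r_displaced_atoms),
                ))
        return sorted(toks)

    identity = tokens(a, {})
    subunits = [su for su in b.subunits]
    for su in subunits:
        if su.stoichiometry > MAX_PERMUTATION_STOICHIOMETRY:
            raise SemanticsError(
                f"copy-permutation search capped at stoichiometry "
                f"{MAX_PERMUTATION_STOICHIOMETRY}; subunit {su.id} has {su.stoichiometry}"
            )
    perm_spaces = [
        list(permutations(range(1, su.stoichiometry + 1))) for su in subunits
    ]
    for combo in product(*perm_spaces):
        assignment = {}
        for su, perm in zip(subunits, combo):
            for copy, mapped in enumerate(perm, start=1):
                assignment[(su.id, copy)] = mapped
        if tokens(b, assignment) == identity:
            return True
    return False


def _diff_complexes(a: Complex, b: Complex) -> list[dict]:
    out = []
    ids_a = {su.id: su for su in a.subunits}
    ids_b = {su.id: su for su in b.subunits}
    for sid in sorted(set(ids_a) | set(ids_b)):
        if sid not in ids_b:
            out.append({"kind": "subunit-removed", "subunit": sid})
        elif sid not in ids_a:
            out.append({"kind": "subunit-added", "subunit": sid})
        else:
            if ids_a[sid].stoichiometry != ids_b[sid].stoichiometry:
                out.append({"kind": "stoichiometry", "subunit": sid,
                            "a": ids_a[sid].stoichiometry, "b": ids_b[sid].stoichiometry})
            if isinstance(ids_a[sid].structure, Polymer) and isinstance(
                ids_b[sid].structure, Polymer
            ):
                for d in _diff_polymers(ids_a[sid].structure, ids_b[sid].structure):
                    d = dict(d)
                    d["subunit"] = sid
                    out.append(d)
    sa = serialize_complex(a)
    sb = serialize_complex(b)
    if not out and sa != sb:
        out.append({"kind": "crosslinks", "a": sa, "b": sb})
    return out


def is_equal(a: Polymer | Complex, b: Polymer | Complex) -> bool:
    """Equality after normalization; complexes up to subunit-copy permutation."""
    if isinstance(a, Complex) and isinstance(b, Complex):
        return _complexes_equal(a, b)
    return not diff(a, b)


# ---------------------------------------------------------------------------
# canonical sequence, FASTA, reference QC

def canonical_sequence(p: Polymer) -> str:
    """Plain IUPAC/IUBMB sequence: base-monomer codes, or the unknown code."""
    out = []
    for occ in p.sequence:
        r = occ.residue
        if r.base_monomers:
            out.append("".join(
                p.alphabet.get_residue(b).code for b in r.base_monomers
            ))
        elif r.code and len(r.code) == 1 and not occ.is_inline:
            out.append(r.code)
        else:
            out.append(p.alphabet.unknown_code)
    return "".join(out)


def export_fasta(polymers: list[tuple[str, Polymer]], path: str | Path) -> None:
    """Write canonical sequences of (id, polymer) pairs as 80-column FASTA."""
    records = [
        SeqRecord(Seq(canonical_sequence(p)), id=name, description="")
        for name, p in polymers
    ]
    with open(path, "w") as handle:
        FastaWriter(handle, wrap=80).write_file(records)


def check_against_reference(p: Polymer, ref: str, offset: int = 0) -> ValidationReport:
    """Compare a polymer against a canonical reference sequence.

    ``offset`` shifts polymer coordinates onto the reference: polymer position
    ``i`` corresponds to reference position ``i + offset`` (e.g. ``offset=1``
    when the reference retains an initiator methionine the polymer lacks).
    Residues with base monomers must sit on one of those monomers; residues
    with no base monomers are wildcards (warning only).
    """
    report = ValidationReport()
    ref = ref.strip().upper()
    if len(p) + offset != len(ref):
        report.error(
            "ref-length", "sequence",
            f"polymer length {len(p)} (+offset {offset}) != reference length {len(ref)}",
        )
    for occ in p.sequence:
        j = occ.position + offset
        if j > len(ref) or j < 1:
            report.error(
                "ref-site", f"residue {occ.position}",
                f"site maps to reference position {j}, outside 1..{len(ref)}",
            )
            continue
        expected = ref[j - 1]
        r = occ.residue
        if r.base_monomers:
            codes = {p.alphabet.get_residue(b).code for b in r.base_monomers}
        elif r.code and len(r.code) == 1 and not occ.is_inline:
            codes = {r.code}
        else:
            report.warn(
                "ref-wildcard", f"residue {occ.position}",
                "residue has no base monomers; treated as a wildcard",
            )
            continue
        if expected not in codes:
            report.error(
                "ref-mismatch", f"residue {occ.position}",
                f"residue maps to {'/'.join(sorted(codes))} but reference has "
                f"{expected} at position {j}",
            )
    return report


def export_smiles(molecule: Polymer | Complex,
                  ontology: CrosslinkOntology | None = None) -> str:
    """SMILES of the assembled molecule; nicked chains give dot-separated parts."""
    return write_smiles(assemble(molecule, ontology))


def normalized_serialization(molecule: Polymer | Complex) -> str:
    """Deterministic text form used by equality (crosslinks sorted)."""
    if isinstance(molecule, Polymer):
        clone = Polymer(
            alphabet=molecule.alphabet, sequence=molecule.sequence,
            nicks=molecule.nicks,
            crosslinks=sorted(molecule.crosslinks,
                              key=lambda xl: _normalized_crosslink_token(xl)),
            circular=molecule.circular, extra_mass=molecule.extra_mass,
            extra_charge=molecule.extra_charge, comments=molecule.comments,
        )
        return serialize_polymer(clone)
    return serialize_complex(molecule)
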
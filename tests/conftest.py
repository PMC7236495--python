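import pytest

from macromol.alphabet import packaged_alphabet, packaged_ontology
from macromol.molgraph import ElementFormula, get_formula


@pytest.fixture(scope="session")
def protein():
    return packaged_alphabet("protein")


@pytest.fixture(scope="session")
def dna():
    return packaged_alphabet("dna")


@pytest.fixture(scope="session")
def rna():
    return packaged_alphabet("rna")


@pytest.fixture(scope="session")
def ontology():
    return packaged_ontology()


def polymer_arithmetic(p, ontology):
    """Independent oracle: (formula, charge) of a polymer by pure bookkeeping.

    Sums residue formulas and subtracts displaced atoms per backbone bond and
    crosslink, without building any molecular graph.  Kept deliberately free
    of the assembly code path it checks.
    """
    total = ElementFormula()
    charge = 0
    for occ in p.sequence:
        total = total + get_formula(occ.residue.structure)
        charge += sum(a.formal_charge for a in occ.residue.structure.atoms)

    def remove(pos, spec):
        nonlocal total, charge
        structure = p.sequence[pos - 1].residue.structure
        if spec.element == "H":
            total_sub = ElementFormula({"H": 1})
            charge_delta = spec.charge_delta
        else:
            atom = structure.atoms[spec.index - 1]
            total_sub = ElementFormula({spec.element: 1})
            if atom.total_h:
                total_sub = total_sub + ElementFormula({"H": atom.total_h})
            charge_delta = -atom.formal_charge
        total = total - total_sub
        charge += charge_delta

    n = len(p.sequence)
    pairs = [(i, i + 1) for i in range(1, n) if i not in p.nicks]
    if p.circular and n not in p.nicks:
        pairs.append((n, 1))
    for i, j in pairs:
        left, right = p.sequence[i - 1].residue, p.sequence[j - 1].residue
        for spec in left.r_displaced_atoms:
            remove(i, spec)
        for spec in right.l_displaced_atoms:
            remove(j, spec)
        for a, b in zip(left.r_bond_atoms, right.l_bond_atoms):
            charge += a.charge_delta + b.charge_delta
    for xl in p.crosslinks:
        if xl.is_typed:
            xt = ontology.get(xl.type_id)
            for spec in xt.l_displaced_atoms:
                remove(xl.l_residue, spec)
            for spec in xt.r_displaced_atoms:
                remove(xl.r_residue, spec)
            for a, b in zip(xt.l_bond_atoms, xt.r_bond_atoms):
                charge += a.charge_delta + b.charge_delta
        else:
            for pos, spec in xl.l_displaced_atoms + xl.r_displaced_atoms:
                remove(pos, spec)
            for (lp, a), (rp, b) in zip(xl.l_bond_atoms, xl.r_bond_atoms):
                charge += a.charge_delta + b.charge_delta
    if p.extra_charge:
        charge += p.extra_charge
    return total, charge
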
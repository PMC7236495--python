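"""SMILES subset parser/writer and molecular properties."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macromol import molgraph as mg


class TestParse:
    def test_glycine_atoms_and_implicit_hydrogens(self):
        g = mg.parse_smiles("NCC(O)=O")
        assert [(a.element, a.implicit_h) for a in g.atoms] == [
            ("N", 2), ("C", 2), ("C", 0), ("O", 1), ("O", 0),
        ]
        orders = sorted(b.order for b in g.bonds)
        assert orders == [1, 1, 1, 2]

    def test_single_bracket_hydrogen_atom(self):
        g = mg.parse_smiles("[H]")
        (atom,) = g.atoms
        assert (atom.element, atom.implicit_h, atom.formal_charge) == ("H", 0, 0)

    def test_ring_closure_builds_triangle(self):
        g = mg.parse_smiles("C1CC1")
        assert len(g.atoms) == 3
        assert len(g.bonds) == 3
        assert all(a.implicit_h == 2 for a in g.atoms)
        assert {b.key() for b in g.bonds} == {
            frozenset((1, 2)), frozenset((2, 3)), frozenset((1, 3)),
        }

    def test_percent_ring_closure(self):
        g = mg.parse_smiles("C%12CC%12")
        assert len(g.bonds) == 3

    def test_dot_separates_components(self):
        g = mg.parse_smiles("O.O")
        assert len(g.atoms) == 2 and not g.bonds

    def test_bracket_charges(self):
        assert mg.get_charge(mg.parse_smiles("[NH4+]")) == 1
        assert mg.get_charge(mg.parse_smiles("[O-]P([O-])(=O)O")) == -2
        assert mg.get_charge(mg.parse_smiles("[Fe+2]")) == 2

    def test_isotope_parses_with_warning(self):
        with pytest.warns(UserWarning, match="isotope"):
            g = mg.parse_smiles("[13CH4]")
        assert str(mg.get_formula(g)) == "CH4"

    def test_aromatic_input_is_kekulized(self):
        g = mg.parse_smiles("c1ccccc1")
        assert sorted(b.order for b in g.bonds) == [1, 1, 1, 2, 2, 2]
        assert str(mg.get_formula(g)) == "C6H6"

    def test_pyrrole_nitrogen_takes_no_double_bond(self):
        g = mg.parse_smiles("c1cc[nH]c1")
        n = next(a for a in g.atoms if a.element == "N")
        assert all(order == 1 for nbr, order in g.neighbors(n.index))
        assert str(mg.get_formula(g)) == "C4H5N"

    def test_unkekulizable_input_rejected(self):
        with pytest.raises(mg.SmilesError, match="kekulize"):
            mg.parse_smiles("c1cccc1")  # five carbons each needing a double bond

    @pytest.mark.parametrize(
        "text,match",
        [
            ("NC(C(O)=O", "unbalanced parentheses"),
            ("CC)", "unbalanced parentheses"),
            ("C1CC", "dangling ring closure"),
            ("[Xx]", "unknown element"),
            ("Xx", "unexpected character"),
            ("C(C)(C)(C)(C)C", "valence overflow"),
            ("", "empty"),
            ("C=", "dangling bond symbol"),
            ("C==C", "consecutive bond symbols"),
        ],
    )
    def test_errors_carry_character_offsets(self, text, match):
        with pytest.raises(mg.SmilesError, match=match):
            mg.parse_smiles(text)


class TestProperties:
    def test_formula_counts_implicit_hydrogens(self):
        assert str(mg.get_formula(mg.parse_smiles("NCC(O)=O"))) == "C2H5NO2"
        assert str(mg.get_formula(mg.parse_smiles("O"))) == "H2O"
        assert str(mg.get_formula(mg.parse_smiles("[Na+]"))) == "Na"

    def test_molecular_weight(self):
        assert mg.get_mol_weight(mg.parse_smiles("NCC(O)=O")) == pytest.approx(75.07, abs=0.01)
        assert mg.get_mol_weight(mg.parse_smiles("O")) == pytest.approx(18.02, abs=0.01)

    def test_weight_of_empty_graph_is_an_error(self):
        with pytest.raises(mg.MolGraphError):
            mg.get_mol_weight(mg.MolecularGraph())

    def test_mw_is_linear_in_formula(self):
        g = mg.parse_smiles("NC(C(O)=O)CC1=CC=C(O)C=C1")
        expected = sum(
            n * mg.ATOMIC_WEIGHTS[e] for e, n in mg.get_formula(g).items()
        )
        assert mg.get_mol_weight(g) == expected

    def test_formula_additivity_over_dot_components(self):
        combined = mg.get_formula(mg.parse_smiles("NCC(O)=O.O.CC"))
        parts = [mg.get_formula(mg.parse_smiles(s)) for s in ("NCC(O)=O", "O", "CC")]
        total = parts[0] + parts[1] + parts[2]
        assert combined == total

    def test_hill_order_rendering(self):
        assert str(mg.ElementFormula({"O": 1, "H": 2})) == "H2O"
        assert str(mg.ElementFormula({"Se": 1, "C": 3, "H": 7, "N": 1, "O": 2})) == "C3H7NO2Se"


class TestAtomAt:
    def test_position_lookup_by_appearance_order(self):
        g = mg.parse_smiles("NCC(O)=O")
        assert mg.atom_at(g, "N", 1).element == "N"
        assert mg.atom_at(g, "O", 4) is g.atoms[3]

    def test_element_mismatch_reports_both_elements(self):
        g = mg.parse_smiles("NCC(O)=O")
        with pytest.raises(mg.MolGraphError, match="expected S, found N"):
            mg.atom_at(g, "S", 1)

    def test_index_out_of_range(self):
        g = mg.parse_smiles("NCC(O)=O")
        with pytest.raises(mg.MolGraphError, match="out of range"):
            mg.atom_at(g, "O", 6)


class TestWrite:
    @pytest.mark.parametrize(
        "text",
        [
            "NCC(O)=O", "C1CC1", "c1ccccc1", "c1cc[nH]c1", "[NH4+]", "[O-]",
            "OP(O)(=O)OCC1OC(N2C=NC3=C2N=CN=C3N)CC1O",
            "NC(C(O)=O)CC1=CNC2=CC=CC=C12", "O.O.CC", "[SeH]C", "N#CC=CC",
        ],
    )
    def test_round_trip_preserves_structure(self, text):
        g = mg.parse_smiles(text)
        s = mg.write_smiles(g)
        assert mg.isomorphic_profile(mg.parse_smiles(s)) == mg.isomorphic_profile(g)

    def test_charged_single_atom_forces_bracket(self):
        g = mg.parse_smiles("[O-]")
        assert mg.write_smiles(g) == "[O-]"

    def test_empty_graph_rejected(self):
        with pytest.raises(mg.MolGraphError):
            mg.write_smiles(mg.MolecularGraph())

    def test_output_is_deterministic(self):
        g = mg.parse_smiles("NC(C(O)=O)CC1=CC=C(O)C=C1")
        assert mg.write_smiles(g) == mg.write_smiles(g)

    def test_long_chain_does_not_hit_recursion_limits(self):
        g = mg.parse_smiles("C" * 2000)
        s = mg.write_smiles(g)
        assert str(mg.get_formula(mg.parse_smiles(s))) == "C2000H4002"


def _random_graph(seed: int) -> mg.MolecularGraph:
    """Random chemically sane graph: spanning tree + extra ring bonds, all
    within the smallest default valence of each element."""
    rng = random.Random(seed)
    elements = ["C", "N", "O", "S", "P", "Cl"]
    budget = {"C": 4, "N": 3, "O": 2, "S": 2, "P": 3, "Cl": 1}
    g = mg.MolecularGraph()
    n = rng.randint(1, 14)
    for _ in range(n):
        g.add_atom(mg.Atom(element=rng.choice(elements)))
    used = {i: 0 for i in range(1, n + 1)}
    for i in range(2, n + 1):
        j = rng.randint(1, i - 1)
        if used[j] < budget[g.atoms[j - 1].element] and used[i] < budget[g.atoms[i - 1].element]:
            g.add_bond(i, j, 1)
            used[i] += 1
            used[j] += 1
    for _ in range(rng.randint(0, 3)):
        i, j = rng.randint(1, n), rng.randint(1, n)
        if i == j or frozenset((i, j)) in {b.key() for b in g.bonds}:
            continue
        if used[i] < budget[g.atoms[i - 1].element] and used[j] < budget[g.atoms[j - 1].element]:
            g.add_bond(i, j, 1)
            used[i] += 1
            used[j] += 1
    for atom in g.atoms:
        atom.implicit_h = budget[atom.element] - used[atom.index]
    return g


@settings(max_examples=150, deadline=None, derandomize=True)
@given(seed=st.integers(min_value=0, max_value=10**6))
def test_write_parse_round_trip_on_random_graphs(seed):
    """write_smiles output re-parses to an isomorphic graph (property)."""
    g = _random_graph(seed)
    s = mg.write_smiles(g)
    g2 = mg.parse_smiles(s)
    assert mg.isomorphic_profile(g2) == mg.isomorphic_profile(g)
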
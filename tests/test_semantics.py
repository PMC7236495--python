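"""Validation rules, molecular assembly, properties, comparison, QC, export."""

import random

import pytest

from conftest import polymer_arithmetic
from macromol import molgraph as mg
from macromol.complexes import parse_complex
from macromol.corpus import CorpusSpec, generate_complex_corpus, generate_corpus
from macromol.polymer import parse_polymer, serialize_polymer
from macromol import semantics as sem


def P(text, alphabet, ontology):
    return parse_polymer(text, alphabet, ontology)


class TestValidationRules:
    def test_clean_tripeptide(self, protein, ontology):
        report = sem.validate_polymer(P("AC{SEC}", protein, ontology), ontology)
        assert report.ok and not report.errors

    def test_interior_left_cap_is_v2(self, protein, ontology):
        report = sem.validate_polymer(P("A{AC}G", protein, ontology), ontology)
        assert "V2" in report.rules()
        assert any("residue 2" in f.location for f in report.errors)

    def test_interior_cap_also_breaks_bondability_v1(self, protein, ontology):
        report = sem.validate_polymer(P("A{AC}G", protein, ontology), ontology)
        assert "V1" in report.rules()

    def test_cap_next_to_nick_is_legal(self, protein, ontology):
        report = sem.validate_polymer(P("AG:{AC}GG", protein, ontology), ontology)
        assert report.ok

    def test_circular_with_right_cap_is_v3(self, protein, ontology):
        report = sem.validate_polymer(P("AG{NH2} | circular", protein, ontology), ontology)
        assert "V3" in report.rules()

    def test_element_mismatched_inline_atom_ref_is_v4(self, protein, ontology):
        text = ('A[id: bad | structure: "NCC(O)=O" | l-bond-atom: S1 | '
                "r-bond-atom: C3 | r-displaced-atom: O4]G")
        report = sem.validate_polymer(P(text, protein, ontology), ontology)
        assert "V4" in report.rules()

    def test_missing_hydrogen_displacement_is_v5(self, protein, ontology):
        text = ('A[id: bad | structure: "NCC(O)=O" | l-bond-atom: N1 | '
                "l-displaced-atom: H3 | r-bond-atom: C3 | r-displaced-atom: O4]G")
        report = sem.validate_polymer(P(text, protein, ontology), ontology)
        assert "V5" in report.rules()

    def test_crosslink_site_beyond_length_is_v6(self, protein, ontology):
        report = sem.validate_polymer(
            P("ACC | x-link: [type: disulfide | l: 2 | r: 9]", protein, ontology),
            ontology,
        )
        assert "V6" in report.rules()

    def test_disulfide_on_alanine_is_v7(self, protein, ontology):
        report = sem.validate_polymer(
            P("AACC | x-link: [type: disulfide | l: 1 | r: 3]", protein, ontology),
            ontology,
        )
        assert "V7" in report.rules()

    def test_doubly_consumed_atom_is_v8(self, protein, ontology):
        report = sem.validate_polymer(
            P("CACAC | x-link: [type: disulfide | l: 1 | r: 3] | "
              "x-link: [type: disulfide | l: 1 | r: 5]", protein, ontology),
            ontology,
        )
        assert "V8" in report.rules()

    def test_bad_position_range_is_v9(self, protein, ontology):
        text = ('AA[id: u | structure: "NCC(O)=O" | l-bond-atom: N1 | '
                "l-displaced-atom: H1 | r-bond-atom: C3 | r-displaced-atom: O4 | "
                "position: 2-9]A")
        report = sem.validate_polymer(P(text, protein, ontology), ontology)
        assert "V9" in report.rules()

    def test_crosslink_spanning_nick_warns(self, protein, ontology):
        report = sem.validate_polymer(
            P("CA:AC | x-link: [type: disulfide | l: 1 | r: 4]", protein, ontology),
            ontology,
        )
        assert report.ok
        assert any("nick" in f.message for f in report.warnings)

    def test_report_text_and_dict_shapes(self, protein, ontology):
        report = sem.validate_polymer(P("A{AC}G", protein, ontology), ontology)
        assert "[V2]" in report.to_text()
        d = report.to_dict()
        assert d["valid"] is False and d["errors"]


class TestComplexValidation:
    def test_fig_dimer_is_clean(self, protein, ontology):
        pep = P("AC{SEC}", protein, ontology)
        cx = parse_complex("2 * pep | x-link: [type: disulfide | l: pep(1)-2 | "
                           "r: pep(2)-2]", {"pep": pep}, ontology)
        assert sem.validate_complex(cx, ontology).ok

    def test_unattached_structure_is_error(self, ontology):
        cx = parse_complex("1 * a + 2 * b", None, ontology)
        report = sem.validate_complex(cx, ontology)
        assert not report.ok

    def test_degenerate_complex_warns(self, protein, ontology):
        cx = parse_complex("1 * a", {"a": P("AAA", protein, ontology)}, ontology)
        report = sem.validate_complex(cx, ontology)
        assert report.ok
        assert any("degenerate" in f.message for f in report.warnings)

    def test_subunit_errors_are_propagated_with_location(self, protein, ontology):
        cx = parse_complex("1 * a + 1 * b",
                           {"a": P("A{AC}G", protein, ontology),
                            "b": P("AAA", protein, ontology)}, ontology)
        report = sem.validate_complex(cx, ontology)
        assert any(f.location.startswith("subunit a") for f in report.errors)

    def test_crosslink_residue_outside_subunit_is_v6(self, protein, ontology):
        pep = P("ACC", protein, ontology)
        cx = parse_complex("2 * pep | x-link: [type: disulfide | l: pep(1)-9 | "
                           "r: pep(2)-2]", {"pep": pep}, ontology)
        assert "V6" in sem.validate_complex(cx, ontology).rules()


class TestAssembly:
    def test_glycylglycine_formula(self, protein, ontology):
        gg = P("GG", protein, ontology)
        assert str(sem.get_formula(gg, ontology)) == "C4H8N2O3"

    def test_fig_dimer_formula_weight_charge(self, protein, ontology):
        pep = P("AC{SEC}", protein, ontology)
        cx = parse_complex("2 * pep | x-link: [type: disulfide | l: pep(1)-2 | "
                           "r: pep(2)-2]", {"pep": pep}, ontology)
        assert str(sem.get_formula(cx, ontology)) == "C18H32N6O8S2Se2"
        assert sem.get_mol_weight(cx, ontology) == pytest.approx(682.56, abs=0.02)
        assert sem.get_net_charge(cx, ontology) == 0

    def test_circular_trimer_loses_three_waters(self, protein, ontology):
        ggg = P("GGG | circular", protein, ontology)
        g = sem.assemble(ggg, ontology)
        assert str(mg.get_formula(g)) == "C6H9N3O3"
        backbone_n_c = [
            b for b in g.bonds
            if {g.atoms[b.a - 1].element, g.atoms[b.b - 1].element} == {"N", "C"}
        ]
        assert len(backbone_n_c) == 6  # 3 intra-residue N-C plus 3 peptide bonds

    def test_extra_mass_and_charge_affect_weight_and_charge_only(self, protein, ontology):
        plain = P("AAA", protein, ontology)
        extra = P("AAA | extra: [mass: 79.97 | charge: -2]", protein, ontology)
        assert sem.get_formula(plain, ontology) == sem.get_formula(extra, ontology)
        assert sem.get_mol_weight(extra, ontology) == pytest.approx(
            sem.get_mol_weight(plain, ontology) + 79.97
        )
        assert sem.get_net_charge(extra, ontology) == sem.get_net_charge(plain, ontology) - 2

    def test_assembling_invalid_polymer_raises(self, protein, ontology):
        with pytest.raises(sem.SemanticsError, match="V2"):
            sem.assemble(P("A{AC}G", protein, ontology), ontology)

    def test_chain_length_law_for_glycine(self, protein, ontology):
        """MW(Gly_n) = n * MW(Gly) - (n - 1) * MW(H2O)."""
        for n in (1, 2, 10, 50):
            p = P("G" * n, protein, ontology)
            expected = n * 75.07 - (n - 1) * 18.02
            assert sem.get_mol_weight(p, ontology) == pytest.approx(expected, abs=0.01 * n)

    def test_formula_conservation_on_random_polymers(self, protein, ontology):
        """Assembled formula/charge equal the independent arithmetic oracle."""
        records = generate_corpus(CorpusSpec(n_records=200, seed=23))
        for text, _ in records:
            p = parse_polymer(text, protein, ontology)
            expected_formula, expected_charge = polymer_arithmetic(p, ontology)
            assert sem.get_formula(p, ontology) == expected_formula, text
            assert sem.get_net_charge(p, ontology) == expected_charge, text

    def test_nick_complex_duality(self, protein, ontology):
        """A nicked polymer equals the complex of its fragments."""
        rng = random.Random(17)
        codes = protein.canonical_codes()
        for _ in range(30):
            n = rng.randint(4, 16)
            seq = "".join(rng.choice(codes) for _ in range(n))
            cut = rng.randint(1, n - 1)
            nicked = parse_polymer(seq[:cut] + ":" + seq[cut:], protein, ontology)
            cx = parse_complex(
                "1 * left + 1 * right",
                {"left": parse_polymer(seq[:cut], protein, ontology),
                 "right": parse_polymer(seq[cut:], protein, ontology)},
                ontology,
            )
            assert sem.get_formula(nicked, ontology) == sem.get_formula(cx, ontology)
            assert sem.get_mol_weight(nicked, ontology) == pytest.approx(
                sem.get_mol_weight(cx, ontology), abs=1e-9
            )
            assert sem.get_net_charge(nicked, ontology) == sem.get_net_charge(cx, ontology)


class TestEquality:
    def test_serialize_parse_image_is_equal(self, protein, ontology):
        p = P("AC{SEC}C | x-link: [type: disulfide | l: 2 | r: 4]", protein, ontology)
        again = parse_polymer(serialize_polymer(p), protein, ontology)
        assert sem.is_equal(p, again)
        assert sem.diff(p, again) == []

    def test_residue_substitution_diff(self, protein, ontology):
        a = P("AC{SEC}", protein, ontology)
        b = P("ACC", protein, ontology)
        d = sem.diff(a, b)
        assert not sem.is_equal(a, b)
        assert any(item["kind"] == "residue" and item["position"] == 3 for item in d)

    def test_inline_residue_matches_alphabet_equivalent(self, protein, ontology):
        inline = P('A[id: g | structure: "NCC(O)=O" | l-bond-atom: N1 | '
                   "l-displaced-atom: H1 | r-bond-atom: C3 | r-displaced-atom: O4]A",
                   protein, ontology)
        named = P("AGA", protein, ontology)
        assert sem.is_equal(inline, named)

    def test_complex_equality_up_to_copy_permutation(self, protein, ontology):
        pep = P("AC{SEC}", protein, ontology)
        a = parse_complex("2 * pep | x-link: [type: disulfide | l: pep(1)-2 | "
                          "r: pep(2)-2]", {"pep": pep}, ontology)
        b = parse_complex("2 * pep | x-link: [type: disulfide | l: pep(2)-2 | "
                          "r: pep(1)-2]", {"pep": pep}, ontology)
        assert sem.is_equal(a, b)
        assert sem.diff(a, b) == []

    def test_different_stoichiometry_not_equal(self, protein, ontology):
        pep = P("ACC", protein, ontology)
        a = parse_complex("2 * pep", {"pep": pep}, ontology)
        b = parse_complex("3 * pep", {"pep": pep}, ontology)
        assert not sem.is_equal(a, b)
        assert any(d["kind"] == "stoichiometry" for d in sem.diff(a, b))

    def test_equality_is_an_equivalence_relation(self, protein, ontology):
        records = generate_corpus(CorpusSpec(n_records=40, seed=31))
        polymers = [parse_polymer(t, protein, ontology) for t, _ in records]
        for p in polymers[:10]:
            assert sem.is_equal(p, p)  # reflexive
        for p, q in zip(polymers, polymers[1:]):
            assert sem.is_equal(p, q) == sem.is_equal(q, p)  # symmetric
            assert (sem.diff(p, q) == []) == sem.is_equal(p, q)


class TestExports:
    def test_canonical_sequence_of_fig_tripeptide(self, protein, ontology):
        assert sem.canonical_sequence(P("AC{SEC}", protein, ontology)) == "ACU"

    def test_modified_residues_map_to_base_monomers(self, protein, ontology):
        assert sem.canonical_sequence(P("A{SEP}D", protein, ontology)) == "ASD"

    def test_cap_maps_to_unknown_code(self, protein, rna, ontology):
        assert sem.canonical_sequence(P("{AC}GG", protein, ontology)) == "XGG"
        assert sem.canonical_sequence(P("{m7G}ACG", rna, ontology)) == "NACG"

    def test_iupac_round_trip_on_canonical_sequences(self, protein, ontology):
        rng = random.Random(41)
        codes = protein.canonical_codes()
        for _ in range(50):
            s = "".join(rng.choice(codes) for _ in range(rng.randint(1, 60)))
            assert sem.canonical_sequence(parse_polymer(s, protein, ontology)) == s

    def test_fasta_export_wraps_at_80_columns(self, protein, ontology, tmp_path):
        long = P("A" * 200, protein, ontology)
        short = P("ACDE", protein, ontology)
        path = tmp_path / "out.fasta"
        sem.export_fasta([("long", long), ("short", short)], path)
        lines = path.read_text().splitlines()
        assert lines[0] == ">long"
        assert max(len(line) for line in lines) <= 80
        from Bio import SeqIO

        records = {r.id: str(r.seq) for r in SeqIO.parse(path, "fasta")}
        assert records == {"long": "A" * 200, "short": "ACDE"}

    def test_export_smiles_formula_round_trip(self, protein, ontology):
        g = P("G", protein, ontology)
        smi = sem.export_smiles(g, ontology)
        assert str(mg.get_formula(mg.parse_smiles(smi))) == "C2H5NO2"

    def test_nicked_polymer_exports_dot_components(self, protein, ontology):
        smi = sem.export_smiles(P("GG:GG", protein, ontology), ontology)
        assert smi.count(".") == 1

    def test_crosslinked_dimer_is_connected(self, protein, ontology):
        pep = P("AC{SEC}", protein, ontology)
        cx = parse_complex("2 * pep | x-link: [type: disulfide | l: pep(1)-2 | "
                           "r: pep(2)-2]", {"pep": pep}, ontology)
        assert "." not in sem.export_smiles(cx, ontology)


class TestReferenceQC:
    def test_phosphoserine_at_tyrosine_position_is_flagged(self, protein, ontology):
        p = P("A{SEP}D", protein, ontology)
        report = sem.check_against_reference(p, "AYD")
        assert any(f.rule == "ref-mismatch" for f in report.errors)

    def test_exact_canonical_match_is_clean(self, protein, ontology):
        p = P("A{SEP}D", protein, ontology)
        assert sem.check_against_reference(p, "ASD").ok

    def test_length_mismatch_is_flagged(self, protein, ontology):
        p = P("ASD", protein, ontology)
        report = sem.check_against_reference(p, "ASDF")
        assert any(f.rule == "ref-length" for f in report.errors)

    def test_initiator_methionine_offset(self, protein, ontology):
        # reference retains the initiator M; the mature chain starts at ref pos 2
        p = P("A{SEP}D", protein, ontology)
        assert not sem.check_against_reference(p, "MASD").ok
        assert sem.check_against_reference(p, "MASD", offset=1).ok

    def test_unknown_origin_residue_is_wildcard_warning(self, protein, ontology):
        p = P("{AC}SD", protein, ontology)
        report = sem.check_against_reference(p, "MSD")
        assert report.ok
        assert any(f.rule == "ref-wildcard" for f in report.warnings)


class TestComplexRoundTrip:
    def test_complex_corpus_round_trip(self, protein, ontology):
        from macromol.complexes import serialize_complex

        for text, subunits in generate_complex_corpus(60, seed=13):
            structures = {
                sid: parse_polymer(s, protein, ontology) for sid, s in subunits.items()
            }
            cx = parse_complex(text, structures, ontology)
            s = serialize_complex(cx)
            again = parse_complex(s, structures, ontology)
            assert serialize_complex(again) == s
            assert sem.is_equal(cx, again)
            assert sem.validate_complex(cx, ontology).ok
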
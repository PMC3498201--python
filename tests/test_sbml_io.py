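"""SBML round trips, legacy-format reading and the table dialects."""

import textwrap

import pytest

from compartgem.model import summarize
from compartgem.sbml_io import (
    DIALECTS,
    parse_formula,
    read_sbml,
    read_table,
    read_validation_suite,
    write_sbml,
    write_table,
)
from compartgem.syngen import generate

# A minimal Level 2 file in the style of legacy constraint-based exports:
# notes-embedded gene association, kinetic-law bound parameters.
LEGACY_SBML = textwrap.dedent(
    """\
    <?xml version="1.0" encoding="UTF-8"?>
    <sbml xmlns="http://www.sbml.org/sbml/level2" level="2" version="1">
      <model id="legacy">
        <listOfCompartments>
          <compartment id="e"/>
          <compartment id="c"/>
        </listOfCompartments>
        <listOfSpecies>
          <species id="M_glc_e" compartment="e"/>
          <species id="M_glc_c" compartment="c"/>
        </listOfSpecies>
        <listOfReactions>
          <reaction id="R_EX_glc" reversible="true">
            <listOfReactants>
              <speciesReference species="M_glc_e" stoichiometry="1"/>
            </listOfReactants>
          </reaction>
          <reaction id="R_GLCt" reversible="false">
            <notes>
              <body xmlns="http://www.w3.org/1999/xhtml">
                <p>GENE_ASSOCIATION: g1 or g2</p>
              </body>
            </notes>
            <listOfReactants>
              <speciesReference species="M_glc_e" stoichiometry="1"/>
            </listOfReactants>
            <listOfProducts>
              <speciesReference species="M_glc_c" stoichiometry="1"/>
            </listOfProducts>
          </reaction>
        </listOfReactions>
      </model>
    </sbml>
    """
)


class TestSBMLRoundTrip:
    def test_generated_model_round_trips_isomorphically(self, tmp_path, syn_models):
        model, _ = syn_models
        path = tmp_path / "m.xml"
        write_sbml(model, path)
        back = read_sbml(path)
        assert sorted(back.reactions) == sorted(model.reactions)
        for rid, rxn in model.reactions.items():
            got = back.reactions[rid]
            assert got.stoichiometry == rxn.stoichiometry
            assert got.reversible == rxn.reversible
            assert (got.lower_bound, got.upper_bound) == (rxn.lower_bound, rxn.upper_bound)
            assert got.rtype == rxn.rtype
            assert got.gpr == rxn.gpr
            assert got.interface == rxn.interface
            assert got.base_reaction_id == rxn.base_reaction_id
        for mid, met in model.metabolites.items():
            got = back.metabolites[mid]
            assert got.formula == met.formula and got.charge == met.charge
        assert back.topology == model.topology
        assert back.currency_list == model.currency_list
        assert back.biomass_reaction_id == model.biomass_reaction_id
        assert sorted(back.interfaces) == sorted(model.interfaces)
        assert sorted(back.gene_products) == sorted(model.gene_products)

    def test_write_is_deterministic(self, tmp_path, syn_model):
        model, _ = syn_model
        a, b = tmp_path / "a.xml", tmp_path / "b.xml"
        write_sbml(model, a)
        write_sbml(model, b)
        assert a.read_bytes() == b.read_bytes()

    def test_empty_model_writes_a_valid_skeleton(self, tmp_path):
        from compartgem.model import Model

        path = tmp_path / "empty.xml"
        write_sbml(Model(id="empty"), path)
        back = read_sbml(path)
        assert back.reactions == {} and back.metabolites == {}

    def test_malformed_xml_raises_with_line(self, tmp_path):
        path = tmp_path / "bad.xml"
        path.write_text("<sbml><unclosed>")
        with pytest.raises(ValueError, match="line"):
            read_sbml(path)

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_sbml(tmp_path / "nope.xml")


class TestLegacyRead:
    def test_level2_fixture_parses(self, tmp_path):
        path = tmp_path / "legacy.xml"
        path.write_text(LEGACY_SBML)
        model = read_sbml(path)
        assert sorted(model.reactions) == ["EX_glc", "GLCt"]
        summary = summarize(model)
        assert summary.n_reactions == 2 and summary.n_exchange == 1

    def test_notes_gene_association_recovered_as_isozymes(self, tmp_path):
        path = tmp_path / "legacy.xml"
        path.write_text(LEGACY_SBML)
        model = read_sbml(path)
        assert model.reactions["GLCt"].gpr == ("or", ["g1", "g2"])

    def test_suffix_stripping_recovers_base_identity(self, tmp_path):
        path = tmp_path / "legacy.xml"
        path.write_text(LEGACY_SBML)
        model = read_sbml(path)
        assert model.metabolites["glc[e]"].base_id == "glc"
        assert model.reactions["GLCt"].rtype == "transport"


class TestFormulaParsing:
    @pytest.mark.parametrize(
        "text,expected",
        [
            ("H2O", {"H": 2, "O": 1}),
            ("C10H12N5O13P3", {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}),
            ("NaCl", {"Na": 1, "Cl": 1}),
        ],
    )
    def test_known_formulae(self, text, expected):
        assert parse_formula(text) == expected

    def test_garbage_rejected(self):
        with pytest.raises(ValueError):
            parse_formula("c6h12")


class TestTables:
    def test_validations_fixture_yields_cases(self, tmp_path):
        path = tmp_path / "suite.csv"
        path.write_text(
            "id,sources,target,expected\n"
            "v1,glc[e],pyr[c],pass\n"
            "v2,glc[e];o2[e],cit[m],pass\n"
            "v3,ala[e],tau[c],fail\n"
        )
        cases = read_validation_suite(path)
        assert len(cases) == 3
        assert cases[1].sources == ("glc[e]", "o2[e]")
        assert cases[2].expected == "fail"

    @pytest.mark.parametrize("dialect", sorted(DIALECTS))
    def test_round_trip_equality(self, tmp_path, dialect):
        spec = DIALECTS[dialect]
        records = [
            {col: ("a;b" if col in spec.list_columns else f"val{i}_{col}")
             for col in spec.required + ("extra_note",)}
            for i in range(3)
        ]
        path = tmp_path / f"{dialect}.csv"
        write_table(records, dialect, path)
        back = read_table(path, dialect)
        assert len(back) == 3
        assert back[0]["extra_note"] == "val0_extra_note"  # unknown col preserved
        for col in spec.list_columns:
            if col in back[0]:
                assert back[0][col] == ("a", "b")

    def test_missing_required_column_named_in_error(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("id,target\nv1,x[c]\n")
        with pytest.raises(ValueError, match="sources"):
            read_table(path, "validations")

    def test_unknown_dialect_rejected(self, tmp_path):
        with pytest.raises(KeyError):
            read_table(tmp_path / "x.csv", "mystery")
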
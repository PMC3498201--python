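"""Balance checks, classification and summary statistics."""

from fractions import Fraction

import pytest

from compartgem.model import (
    Model,
    Reaction,
    check_charge_balance,
    check_enzyme_compartment_uniqueness,
    check_mass_balance,
    classify_reaction,
    gpr_to_string,
    parse_gpr,
    split_met_id,
    summarize,
    validate_model,
)


def _model_with(mets, reactions=()):
    m = Model()
    for base, comp, formula, charge in mets:
        m.add_metabolite(base, comp, formula=formula, charge=charge)
    for r in reactions:
        m.add_reaction(r)
    return m


# ATP hydrolysis with pH 7.2 ionisation: ATP^4- + H2O -> ADP^3- + HPO4^2- + H+
ATP = {"C": 10, "H": 12, "N": 5, "O": 13, "P": 3}
ADP = {"C": 10, "H": 12, "N": 5, "O": 10, "P": 2}
HPO4 = {"H": 1, "O": 4, "P": 1}


class TestMassBalance:
    def test_transport_of_identical_species_is_balanced(self):
        m = _model_with([("A", "c", {"C": 1, "H": 4}, 0), ("A", "n", {"C": 1, "H": 4}, 0)])
        r = Reaction("t", {"A[c]": Fraction(-1), "A[n]": Fraction(1)}, rtype="transport")
        assert check_mass_balance(r, m.metabolites).balanced

    def test_atp_hydrolysis_is_mass_and_charge_balanced(self):
        # element sums checked by hand: C10 H14 N5 O14 P3 on both sides, net charge -4
        m = _model_with(
            [
                ("atp", "c", ATP, -4),
                ("h2o", "c", {"H": 2, "O": 1}, 0),
                ("adp", "c", ADP, -3),
                ("pi", "c", HPO4, -2),
                ("h", "c", {"H": 1}, 1),
            ]
        )
        r = Reaction(
            "atpase",
            {
                "atp[c]": Fraction(-1),
                "h2o[c]": Fraction(-1),
                "adp[c]": Fraction(1),
                "pi[c]": Fraction(1),
                "h[c]": Fraction(1),
            },
        )
        assert check_mass_balance(r, m.metabolites).balanced
        assert check_charge_balance(r, m.metabolites).balanced

    def test_single_atom_defect_is_reported(self):
        m = _model_with([("A", "c", {"C": 1, "H": 4}, 0), ("B", "c", {"C": 1, "H": 4, "O": 1}, 0)])
        r = Reaction("r", {"A[c]": Fraction(-1), "B[c]": Fraction(1)})
        report = check_mass_balance(r, m.metabolites)
        assert report.status == "imbalanced"
        assert report.imbalance == {"O": Fraction(1)}

    def test_missing_formula_is_unverifiable_not_silent(self):
        m = _model_with([("A", "c", None, 0), ("B", "c", {"C": 1}, 0)])
        r = Reaction("r", {"A[c]": Fraction(-1), "B[c]": Fraction(1)})
        report = check_mass_balance(r, m.metabolites)
        assert report.status == "unverifiable"
        assert report.missing == ("A[c]",)

    def test_boundary_pseudo_reactions_not_applicable(self):
        m = _model_with([("A", "e", {"C": 1}, 0)])
        r = Reaction("EX_A", {"A[e]": Fraction(-1)}, rtype="exchange")
        assert check_mass_balance(r, m.metabolites).status == "not_applicable"
        assert check_charge_balance(r, m.metabolites).status == "not_applicable"

    def test_negating_coefficients_negates_the_report(self):
        m = _model_with([("A", "c", {"C": 2, "H": 6}, 0), ("B", "c", {"C": 2, "H": 4}, 0)])
        r = Reaction("r", {"A[c]": Fraction(-1), "B[c]": Fraction(1)})
        rneg = Reaction("rneg", {k: -v for k, v in r.stoichiometry.items()})
        rep, repneg = (check_mass_balance(x, m.metabolites) for x in (r, rneg))
        assert {k: -v for k, v in rep.imbalance.items()} == dict(repneg.imbalance)


class TestChargeBalance:
    @pytest.mark.parametrize(
        "charges,expected_net",
        [((0, 0), 0), ((-1, 0), 1)],
    )
    def test_simple_conversions(self, charges, expected_net):
        m = _model_with([("A", "c", {"C": 1}, charges[0]), ("B", "c", {"C": 1}, charges[1])])
        r = Reaction("r", {"A[c]": Fraction(-1), "B[c]": Fraction(1)})
        report = check_charge_balance(r, m.metabolites)
        net = report.imbalance.get("charge", Fraction(0))
        assert net == expected_net


class TestClassify:
    def test_single_extracellular_metabolite_is_exchange(self):
        m = _model_with([("glc", "e", None, None)])
        r = Reaction("r", {"glc[e]": Fraction(-1)})
        assert classify_reaction(r, m.metabolites) == "exchange"

    def test_cross_compartment_is_transport(self):
        m = _model_with([("pyr", "c", None, None), ("pyr", "m", None, None)])
        r = Reaction("r", {"pyr[c]": Fraction(-1), "pyr[m]": Fraction(1)})
        assert classify_reaction(r, m.metabolites) == "transport"

    def test_single_compartment_is_metabolic(self):
        m = _model_with([("A", "c", None, None), ("B", "c", None, None)])
        r = Reaction("r", {"A[c]": Fraction(-1), "B[c]": Fraction(1)})
        assert classify_reaction(r, m.metabolites) == "metabolic"

    def test_unknown_metabolite_errors_with_its_id(self):
        m = _model_with([("A", "c", None, None)])
        r = Reaction("r", {"A[c]": Fraction(-1), "ghost[c]": Fraction(1)})
        with pytest.raises(KeyError, match="ghost"):
            classify_reaction(r, m.metabolites)


class TestSummary:
    def test_empty_model_is_all_zeros(self):
        s = summarize(Model())
        assert s.n_metabolites == s.n_reactions == s.n_genes == 0
        assert s.n_gene_associated + s.n_non_gene_associated == s.n_reactions

    def test_multiplicity_groups_on_base_reaction(self):
        m = _model_with([("A", "c", None, None), ("B", "c", None, None),
                         ("A", "m", None, None), ("B", "m", None, None)])
        for comp in ("c", "m"):
            m.add_reaction(
                Reaction(
                    f"R1_{comp}",
                    {f"A[{comp}]": Fraction(-1), f"B[{comp}]": Fraction(1)},
                    base_reaction_id="R1",
                )
            )
        s = summarize(m)
        assert s.n_base_reactions == 1
        assert s.multiplicity == {"1": 0.0, "2": 1.0, "3": 0.0, ">3": 0.0}

    def test_summary_invariant_under_reaction_reordering(self, syn_model):
        model, _ = syn_model
        s1 = summarize(model)
        reordered = model.copy()
        reordered.reactions = dict(reversed(list(reordered.reactions.items())))
        assert summarize(reordered) == s1

    def test_gene_counts_sum_to_total(self, syn_models):
        model, _ = syn_models
        s = summarize(model)
        assert s.n_gene_associated + s.n_non_gene_associated == s.n_reactions


class TestStructure:
    def test_generated_models_validate_cleanly(self, syn_models):
        model, _ = syn_models
        assert validate_model(model) == []

    def test_enzyme_in_two_compartments_is_flagged(self):
        m = _model_with(
            [("A", "c", None, None), ("B", "c", None, None),
             ("A", "m", None, None), ("B", "m", None, None)]
        )
        from compartgem.model import GeneProduct

        m.gene_products["g1"] = GeneProduct("g1", compartment="c")
        for comp in ("c", "m"):
            m.add_reaction(
                Reaction(
                    f"R_{comp}",
                    {f"A[{comp}]": Fraction(-1), f"B[{comp}]": Fraction(1)},
                    gpr="g1",
                )
            )
        issues = check_enzyme_compartment_uniqueness(m)
        assert len(issues) == 1 and "g1" in issues[0]

    def test_zero_coefficient_rejected(self):
        with pytest.raises(ValueError, match="zero coefficient"):
            Reaction("r", {"A[c]": Fraction(0)})

    def test_met_id_round_trip(self):
        assert split_met_id("3pg[c]") == ("3pg", "c")
        with pytest.raises(ValueError):
            split_met_id("nosuffix")


class TestGPR:
    @pytest.mark.parametrize(
        "text",
        ["g1", "g1 or g2", "g1 and g2", "(g1 and g2) or g3", "g1 or (g2 and (g3 or g4))"],
    )
    def test_parse_then_print_round_trips(self, text):
        tree = parse_gpr(text)
        assert parse_gpr(gpr_to_string(tree)) == tree

    def test_empty_gpr_is_none(self):
        assert parse_gpr("") is None
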
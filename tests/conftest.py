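"""Shared hand-built toy models and generator fixtures."""

from __future__ import annotations

from fractions import Fraction

import pytest

from compartgem.model import Model, Reaction
from compartgem.syngen import GenSpec, generate


def build_chain_model() -> Model:
    """EX_A <-> A[e] -> A[c] -> biomass; the single path forces EX_A = -rate."""
    m = Model(id="chain")
    m.add_compartment("e")
    m.add_compartment("c")
    m.add_metabolite("A", "e", formula={"C": 1, "H": 4}, charge=0)
    m.add_metabolite("A", "c", formula={"C": 1, "H": 4}, charge=0)
    m.add_reaction(
        Reaction("EX_A", {"A[e]": Fraction(-1)}, reversible=True, rtype="exchange")
    )
    m.add_reaction(
        Reaction(
            "T_A",
            {"A[e]": Fraction(-1), "A[c]": Fraction(1)},
            reversible=False,
            rtype="transport",
        )
    )
    m.add_reaction(
        Reaction("BIOMASS", {"A[c]": Fraction(-1)}, reversible=False, rtype="biomass")
    )
    m.biomass_reaction_id = "BIOMASS"
    m.topology = {frozenset(("e", "c"))}
    return m


def build_parallel_model() -> Model:
    """Two substrates: route B needs 2 uptakes per biomass, route C needs 1."""
    m = Model(id="parallel")
    m.add_compartment("e")
    m.add_compartment("c")
    for base in ("B", "C"):
        m.add_metabolite(base, "e")
        m.add_metabolite(base, "c")
        m.add_reaction(
            Reaction(f"EX_{base}", {f"{base}[e]": Fraction(-1)}, reversible=True, rtype="exchange")
        )
        m.add_reaction(
            Reaction(
                f"T_{base}",
                {f"{base}[e]": Fraction(-1), f"{base}[c]": Fraction(1)},
                reversible=False,
                rtype="transport",
            )
        )
    m.add_metabolite("P", "c")
    m.add_reaction(
        Reaction(
            "R_fromB",
            {"B[c]": Fraction(-2), "P[c]": Fraction(1)},
            reversible=False,
        )
    )
    m.add_reaction(
        Reaction(
            "R_fromC",
            {"C[c]": Fraction(-1), "P[c]": Fraction(1)},
            reversible=False,
        )
    )
    m.add_reaction(
        Reaction("BIOMASS", {"P[c]": Fraction(-1)}, reversible=False, rtype="biomass")
    )
    m.biomass_reaction_id = "BIOMASS"
    m.topology = {frozenset(("e", "c"))}
    return m


def build_orphan_model() -> Model:
    """Biomass precursor with no producing path: always infeasible."""
    m = Model(id="orphan")
    m.add_compartment("e")
    m.add_compartment("c")
    m.add_metabolite("A", "e")
    m.add_metabolite("Q", "c")
    m.add_reaction(
        Reaction("EX_A", {"A[e]": Fraction(-1)}, reversible=True, rtype="exchange")
    )
    m.add_reaction(
        Reaction("BIOMASS", {"Q[c]": Fraction(-1)}, reversible=False, rtype="biomass")
    )
    m.biomass_reaction_id = "BIOMASS"
    m.topology = {frozenset(("e", "c"))}
    return m


@pytest.fixture
def chain_model() -> Model:
    return build_chain_model()


@pytest.fixture
def parallel_model() -> Model:
    return build_parallel_model()


@pytest.fixture
def orphan_model() -> Model:
    return build_orphan_model()


@pytest.fixture
def syn_model():
    return generate(GenSpec(seed=11))


@pytest.fixture(params=[0, 1, 2])
def syn_models(request):
    return generate(GenSpec(seed=request.param))
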
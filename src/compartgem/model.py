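"""Domain types for a compartmentalised, surface-oriented metabolic model.

A :class:`Model` holds compartments, membrane interfaces, metabolites,
reactions and gene products, together with a compartment adjacency topology.
Stoichiometric coefficients are stored as exact :class:`fractions.Fraction`
values so that mass- and charge-balance checks are free of float drift; they
are converted to floats only when a linear program is built.

Reaction classification follows the usual constraint-based conventions:

``exchange``
    boundary pseudo-reaction touching a single extracellular metabolite;
    by sign convention its flux is negative for influx, positive for efflux.
``transport``
    moves metabolites between at least two compartments.
``metabolic``
    ordinary biochemical conversion inside one compartment.
``biomass``
    the growth pseudo-reaction consuming precursor metabolites.
``demand``
    an auxiliary sink used by synthesis probes.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Mapping

from .constants import (
    COMPARTMENT_NAMES,
    CURRENCY_METABOLITES,
    DEFAULT_BOUND,
    DEFAULT_INTERFACES,
    DEFAULT_TOPOLOGY,
    EXTRACELLULAR,
)

_MET_ID_RE = re.compile(r"^(?P<base>.+)\[(?P<comp>[^\[\]]+)\]$")


def met_id(base_id: str, compartment: str) -> str:
    """Compose a metabolite id from its chemical identity and compartment."""
    return f"{base_id}[{compartment}]"


def split_met_id(metabolite_id: str) -> tuple[str, str]:
    """Split ``base[comp]`` into ``(base, comp)``.

    Raises ``ValueError`` if the id does not follow the suffix convention.
    """
    m = _MET_ID_RE.match(metabolite_id)
    if m is None:
        raise ValueError(f"metabolite id {metabolite_id!r} lacks a [compartment] suffix")
    return m.group("base"), m.group("comp")


@dataclass(frozen=True)
class Compartment:
    id: str
    name: str = ""
    kind: str = "intracellular"  # or "extracellular"

    def __post_init__(self) -> None:
        if self.kind not in ("intracellular", "extracellular"):
            raise ValueError(f"unknown compartment kind {self.kind!r}")


@dataclass(frozen=True)
class Interface:
    """A membrane face or lumen on which a reaction's active site sits.

    ``membrane_of`` names the compartment whose membrane carries the enzyme;
    ``facing`` names the compartment whose metabolite pool the active site
    draws from.  Lumen (soluble) interfaces have ``membrane_of == facing``.
    """

    id: str
    membrane_of: str
    facing: str
    is_lumen: bool = False

    def __post_init__(self) -> None:
        if not self.is_lumen and self.membrane_of == self.facing:
            raise ValueError(
                f"membrane interface {self.id!r} cannot face its own compartment"
            )


@dataclass(frozen=True)
class Metabolite:
    id: str
    base_id: str
    compartment: str
    name: str = ""
    formula: Mapping[str, int] | None = None  # element -> atom count
    charge: int | None = None  # at pH 7.2
    is_currency: bool = False


@dataclass(frozen=True)
class GeneProduct:
    id: str
    symbol: str = ""
    compartment: str | None = None  # each enzyme lives in exactly one compartment


#: GPR expressions are boolean trees: a gene id string, or a tuple
#: ("and"|"or", [children...]).  ``None`` means non-gene-associated.
GPR = object


def gpr_genes(gpr) -> frozenset[str]:
    """Collect the gene ids referenced by a GPR expression."""
    if gpr is None:
        return frozenset()
    if isinstance(gpr, str):
        return frozenset([gpr])
    op, children = gpr
    out: set[str] = set()
    for child in children:
        out |= gpr_genes(child)
    return frozenset(out)


def gpr_to_string(gpr) -> str:
    if gpr is None:
        return ""
    if isinstance(gpr, str):
        return gpr
    op, children = gpr
    joiner = f" {op} "
    return "(" + joiner.join(gpr_to_string(c) for c in children) + ")"


def parse_gpr(text: str):
    """Parse ``"g1 or (g2 and g3)"`` into a GPR tree.  Empty text -> None."""
    tokens = re.findall(r"\(|\)|[Aa][Nn][Dd]|[Oo][Rr]|[^\s()]+", text or "")
    if not tokens:
        return None
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def parse_or():
        nonlocal pos
        terms = [parse_and()]
        while peek() is not None and peek().lower() == "or":
            pos += 1
            terms.append(parse_and())
        return terms[0] if len(terms) == 1 else ("or", terms)

    def parse_and():
        nonlocal pos
        terms = [parse_atom()]
        while peek() is not None and peek().lower() == "and":
            pos += 1
            terms.append(parse_atom())
        return terms[0] if len(terms) == 1 else ("and", terms)

    def parse_atom():
        nonlocal pos
        tok = peek()
        if tok == "(":
            pos += 1
            inner = parse_or()
            if peek() != ")":
                raise ValueError(f"unbalanced parentheses in GPR {text!r}")
            pos += 1
            return inner
        if tok in (")", None) or tok.lower() in ("and", "or"):
            raise ValueError(f"malformed GPR {text!r}")
        pos += 1
        return tok

    tree = parse_or()
    if pos != len(tokens):
        raise ValueError(f"trailing tokens in GPR {text!r}")
    return tree


@dataclass
class Reaction:
    id: str
    stoichiometry: dict[str, Fraction]  # metabolite id -> signed coefficient
    reversible: bool = True
    lower_bound: float | None = None
    upper_bound: float | None = None
    rtype: str = "metabolic"
    base_reaction_id: str | None = None
    interface: str | None = None  # Interface id, or None for lumen default
    gpr: object = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"reaction {self.id!r} has empty stoichiometry")
        clean: dict[str, Fraction] = {}
        for mid, coeff in self.stoichiometry.items():
            frac = coeff if isinstance(coeff, Fraction) else Fraction(coeff)
            if frac == 0:
                raise ValueError(f"reaction {self.id!r} has a zero coefficient for {mid!r}")
            clean[mid] = frac
        self.stoichiometry = clean
        if self.lower_bound is None:
            self.lower_bound = -DEFAULT_BOUND if self.reversible else 0.0
        if self.upper_bound is None:
            self.upper_bound = DEFAULT_BOUND
        if self.base_reaction_id is None:
            self.base_reaction_id = self.id
        if self.rtype not in ("metabolic", "transport", "exchange", "biomass", "demand"):
            raise ValueError(f"unknown reaction type {self.rtype!r}")

    @property
    def reactants(self) -> dict[str, Fraction]:
        return {m: -c for m, c in self.stoichiometry.items() if c < 0}

    @property
    def products(self) -> dict[str, Fraction]:
        return {m: c for m, c in self.stoichiometry.items() if c > 0}

    @property
    def genes(self) -> frozenset[str]:
        return gpr_genes(self.gpr)


@dataclass
class Model:
    """A compartmentalised metabolic model."""

    id: str = "model"
    compartments: dict[str, Compartment] = field(default_factory=dict)
    interfaces: dict[str, Interface] = field(default_factory=dict)
    metabolites: dict[str, Metabolite] = field(default_factory=dict)
    reactions: dict[str, Reaction] = field(default_factory=dict)
    gene_products: dict[str, GeneProduct] = field(default_factory=dict)
    topology: set[frozenset[str]] = field(default_factory=set)
    biomass_reaction_id: str | None = None
    currency_list: frozenset[str] = CURRENCY_METABOLITES
    notes: dict[str, str] = field(default_factory=dict)

    # -- construction helpers -------------------------------------------------

    def add_compartment(self, cid: str, name: str | None = None, kind: str | None = None) -> Compartment:
        if kind is None:
            kind = "extracellular" if cid == EXTRACELLULAR else "intracellular"
        comp = Compartment(cid, name or COMPARTMENT_NAMES.get(cid, cid), kind)
        self.compartments[cid] = comp
        return comp

    def add_metabolite(
        self,
        base_id: str,
        compartment: str,
        *,
        name: str = "",
        formula: Mapping[str, int] | None = None,
        charge: int | None = None,
    ) -> Metabolite:
        mid = met_id(base_id, compartment)
        if compartment not in self.compartments:
            self.add_compartment(compartment)
        met = Metabolite(
            id=mid,
            base_id=base_id,
            compartment=compartment,
            name=name or base_id,
            formula=dict(formula) if formula is not None else None,
            charge=charge,
            is_currency=base_id in self.currency_list,
        )
        self.metabolites[mid] = met
        return met

    def add_reaction(self, reaction: Reaction) -> Reaction:
        for mid in reaction.stoichiometry:
            if mid not in self.metabolites:
                raise KeyError(f"reaction {reaction.id!r} references unknown metabolite {mid!r}")
        self.reactions[reaction.id] = reaction
        return reaction

    def copy(self) -> "Model":
        clone = Model(
            id=self.id,
            compartments=dict(self.compartments),
            interfaces=dict(self.interfaces),
            metabolites=dict(self.metabolites),
            reactions={rid: replace(r, stoichiometry=dict(r.stoichiometry)) for rid, r in self.reactions.items()},
            gene_products=dict(self.gene_products),
            topology=set(self.topology),
            biomass_reaction_id=self.biomass_reaction_id,
            currency_list=self.currency_list,
            notes=dict(self.notes),
        )
        return clone

    # -- queries --------------------------------------------------------------

    def reaction_compartments(self, reaction: Reaction) -> frozenset[str]:
        return frozenset(self.metabolites[m].compartment for m in reaction.stoichiometry)

    def exchange_reactions(self) -> list[Reaction]:
        return [r for r in self.reactions.values() if r.rtype == "exchange"]

    def default_interfaces(self) -> None:
        """Install the standard 18-interface layout for declared compartments."""
        for iid, membrane_of, facing, is_lumen in DEFAULT_INTERFACES:
            if membrane_of in self.compartments and facing in self.compartments:
                self.interfaces[iid] = Interface(iid, membrane_of, facing, is_lumen)

    def default_topology(self) -> None:
        """Install the standard adjacency restricted to declared compartments."""
        for edge in DEFAULT_TOPOLOGY:
            if all(c in self.compartments for c in edge):
                self.topology.add(edge)


# -- balance checks ----------------------------------------------------------


@dataclass(frozen=True)
class BalanceReport:
    """Outcome of a mass or charge balance check.

    ``status`` is one of ``balanced``, ``imbalanced``, ``not_applicable``
    (boundary pseudo-reactions are never checked) or ``unverifiable`` (a
    participating metabolite lacks a formula or charge).
    """

    status: str
    imbalance: Mapping[str, Fraction] = field(default_factory=dict)
    missing: tuple[str, ...] = ()

    @property
    def balanced(self) -> bool:
        return self.status == "balanced"


_SKIP_BALANCE = ("exchange", "biomass", "demand")


def check_mass_balance(reaction: Reaction, metabolites: Mapping[str, Metabolite]) -> BalanceReport:
    """Per-element net atom count of a reaction; empty imbalance = balanced.

    Boundary pseudo-reactions (exchange, biomass, demand) are intrinsically
    unbalanced and report ``not_applicable``.  A metabolite without a formula
    makes the check ``unverifiable`` — never a silent pass.
    """
    if reaction.rtype in _SKIP_BALANCE:
        return BalanceReport("not_applicable")
    missing = tuple(
        sorted(m for m in reaction.stoichiometry if metabolites[m].formula is None)
    )
    if missing:
        return BalanceReport("unverifiable", missing=missing)
    net: dict[str, Fraction] = {}
    for mid, coeff in reaction.stoichiometry.items():
        for element, count in metabolites[mid].formula.items():
            net[element] = net.get(element, Fraction(0)) + coeff * count
    imbalance = {el: v for el, v in sorted(net.items()) if v != 0}
    return BalanceReport("imbalanced" if imbalance else "balanced", imbalance=imbalance)


def check_charge_balance(reaction: Reaction, metabolites: Mapping[str, Metabolite]) -> BalanceReport:
    """Net charge of a reaction under the pH 7.2 ionisation convention."""
    if reaction.rtype in _SKIP_BALANCE:
        return BalanceReport("not_applicable")
    missing = tuple(
        sorted(m for m in reaction.stoichiometry if metabolites[m].charge is None)
    )
    if missing:
        return BalanceReport("unverifiable", missing=missing)
    net = sum(
        (coeff * metabolites[mid].charge for mid, coeff in reaction.stoichiometry.items()),
        Fraction(0),
    )
    imbalance = {"charge": net} if net != 0 else {}
    return BalanceReport("imbalanced" if imbalance else "balanced", imbalance=imbalance)


def classify_reaction(
    reaction: Reaction,
    metabolites: Mapping[str, Metabolite],
    biomass_reaction_id: str | None = None,
) -> str:
    """Infer a reaction's type from its stoichiometry."""
    comps = set()
    for mid in reaction.stoichiometry:
        if mid not in metabolites:
            raise KeyError(f"reaction {reaction.id!r} references unknown metabolite {mid!r}")
        comps.add(metabolites[mid].compartment)
    if biomass_reaction_id is not None and reaction.id == biomass_reaction_id:
        return "biomass"
    if len(reaction.stoichiometry) == 1:
        (only_mid,) = reaction.stoichiometry
        if metabolites[only_mid].compartment == EXTRACELLULAR:
            return "exchange"
        return "demand"
    if len(comps) >= 2:
        return "transport"
    return "metabolic"


# -- validation & summary ----------------------------------------------------


def validate_model(model: Model) -> list[str]:
    """Structural consistency check; returns a list of human-readable issues.

    Checks reference resolution, exchange-reaction shape, bound/reversibility
    coherence, same-base formula/charge agreement, topology symmetry (the
    symmetric closure is implied by unordered pairs, so only token validity is
    checked), enzyme-compartment uniqueness, and the surface-orientation rule:
    a non-transport membrane reaction must draw all its metabolites from the
    compartment its interface faces.
    """
    issues: list[str] = []
    for mid, met in model.metabolites.items():
        if met.compartment not in model.compartments:
            issues.append(f"metabolite {mid}: unknown compartment {met.compartment!r}")
        base, comp = split_met_id(mid)
        if base != met.base_id or comp != met.compartment:
            issues.append(f"metabolite {mid}: id does not match base_id/compartment fields")
    by_base: dict[str, Metabolite] = {}
    for met in model.metabolites.values():
        ref = by_base.setdefault(met.base_id, met)
        if (ref.formula, ref.charge) != (met.formula, met.charge):
            issues.append(
                f"metabolite base {met.base_id!r}: formula/charge differ between compartments"
            )
    for rid, rxn in model.reactions.items():
        for mid in rxn.stoichiometry:
            if mid not in model.metabolites:
                issues.append(f"reaction {rid}: unknown metabolite {mid!r}")
        for gid in rxn.genes:
            if gid not in model.gene_products:
                issues.append(f"reaction {rid}: unknown gene product {gid!r}")
        if rxn.reversible and not (rxn.lower_bound < 0 < rxn.upper_bound):
            issues.append(f"reaction {rid}: reversible but bounds do not straddle zero")
        if not rxn.reversible and rxn.lower_bound < 0:
            issues.append(f"reaction {rid}: irreversible but lower bound is negative")
        if rxn.rtype == "exchange":
            if len(rxn.stoichiometry) != 1:
                issues.append(f"reaction {rid}: exchange must touch exactly one metabolite")
            else:
                (mid,) = rxn.stoichiometry
                if mid in model.metabolites and model.metabolites[mid].compartment != EXTRACELLULAR:
                    issues.append(f"reaction {rid}: exchange metabolite {mid} is not extracellular")
        if rxn.interface is not None and rxn.interface in model.interfaces:
            iface = model.interfaces[rxn.interface]
            if rxn.rtype not in ("transport", "exchange") and not iface.is_lumen:
                comps = {
                    model.metabolites[m].compartment
                    for m in rxn.stoichiometry
                    if m in model.metabolites
                }
                if comps != {iface.facing}:
                    issues.append(
                        f"reaction {rid}: membrane interface faces {iface.facing!r} but "
                        f"metabolites live in {sorted(comps)}"
                    )
        elif rxn.interface is not None:
            issues.append(f"reaction {rid}: unknown interface {rxn.interface!r}")
    if model.biomass_reaction_id is not None:
        bio = model.reactions.get(model.biomass_reaction_id)
        if bio is None:
            issues.append(f"biomass reaction {model.biomass_reaction_id!r} not found")
        elif bio.rtype != "biomass":
            issues.append(f"biomass reaction {bio.id} has rtype {bio.rtype!r}")
    for edge in model.topology:
        if len(edge) != 2:
            issues.append(f"topology edge {sorted(edge)} is not a pair")
        for cid in edge:
            if cid not in model.compartments:
                issues.append(f"topology references unknown compartment {cid!r}")
    issues.extend(check_enzyme_compartment_uniqueness(model))
    return issues


def check_enzyme_compartment_uniqueness(model: Model) -> list[str]:
    """Every gene product may catalyse reactions in at most one compartment."""
    issues: list[str] = []
    gene_comps: dict[str, set[str]] = {}
    for rxn in model.reactions.values():
        comps = model.reaction_compartments(rxn)
        for gid in rxn.genes:
            gene_comps.setdefault(gid, set()).update(comps)
    for gid, comps in sorted(gene_comps.items()):
        comps.discard(EXTRACELLULAR)
        if len(comps) > 1:
            issues.append(
                f"gene product {gid}: associated reactions span compartments {sorted(comps)}"
            )
    return issues


@dataclass(frozen=True)
class ModelSummary:
    n_metabolites: int
    n_reactions: int
    n_gene_associated: int
    n_non_gene_associated: int
    n_transport: int
    n_exchange: int
    n_genes: int
    n_compartments: int
    n_interfaces: int
    n_base_reactions: int
    n_compartment_specific: int
    n_surface_specific: int
    multiplicity: Mapping[str, float]  # "1","2","3",">3" -> fraction of base reactions

    def as_dict(self) -> dict:
        return {
            "metabolites": self.n_metabolites,
            "reactions": self.n_reactions,
            "gene_associated": self.n_gene_associated,
            "non_gene_associated": self.n_non_gene_associated,
            "transport": self.n_transport,
            "exchange": self.n_exchange,
            "genes": self.n_genes,
            "compartments": self.n_compartments,
            "interfaces": self.n_interfaces,
            "base_reactions": self.n_base_reactions,
            "compartment_specific_reactions": self.n_compartment_specific,
            "surface_specific_reactions": self.n_surface_specific,
            "multiplicity": dict(self.multiplicity),
        }


def summarize(model: Model) -> ModelSummary:
    """Descriptive statistics of a model; invariant under reaction order."""
    rxns = list(model.reactions.values())
    gene_assoc = [r for r in rxns if r.genes]
    base_comps: dict[str, set[str]] = {}
    surface_keys: set[tuple[str, str | None]] = set()
    for r in rxns:
        comps = model.reaction_compartments(r)
        base_comps.setdefault(r.base_reaction_id, set()).update(comps)
        surface_keys.add((r.id, r.interface))
    n_base = len(base_comps)
    mult_counts = {"1": 0, "2": 0, "3": 0, ">3": 0}
    for comps in base_comps.values():
        k = len(comps)
        key = str(k) if k <= 3 else ">3"
        mult_counts[key] += 1
    multiplicity = {
        key: (count / n_base if n_base else 0.0) for key, count in mult_counts.items()
    }
    return ModelSummary(
        n_metabolites=len(model.metabolites),
        n_reactions=len(rxns),
        n_gene_associated=len(gene_assoc),
        n_non_gene_associated=len(rxns) - len(gene_assoc),
        n_transport=sum(1 for r in rxns if r.rtype == "transport"),
        n_exchange=sum(1 for r in rxns if r.rtype == "exchange"),
        n_genes=len(model.gene_products),
        n_compartments=len(model.compartments),
        n_interfaces=len(model.interfaces),
        n_base_reactions=n_base,
        n_compartment_specific=len(rxns),
        n_surface_specific=len(surface_keys),
        multiplicity=multiplicity,
    )
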
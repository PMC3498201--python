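"""Deterministic generator of small compartmentalised test models.

The generator emulates the structure of a compartmentalised genome-scale
reconstruction at toy scale: an extracellular space with nutrient exchange
reactions (negative flux = influx), a cytoplasm, a configurable number of
organelles stitched along the physical compartment topology, a biomass
reaction consuming precursors from several compartments, cofactor (currency)
couplings wired as an ATP/ADP regeneration loop, and optionally a blocked
dead-end branch so reachability analyses have a known negative.

Construction is backbone-first: each nutrient feeds a linear pathway that
crosses compartments through dedicated transporters and ends in a biomass
precursor.  Because extra random reactions are confined within compartments,
every inter-compartment transporter on a backbone is the unique route for
its metabolite — which makes planted transporter gaps exactly recoverable
and gives exact ground truth for reachability, uniqueness and essentiality.

Everything is driven by one seeded PRNG; the same spec and seed give an
identical model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from .constants import DEFAULT_BOUND
from .gapfill import CandidateTransporter
from .model import GeneProduct, Model, Reaction, met_id

#: Order in which compartments are drawn; respects the adjacency rule that
#: the mitochondrial matrix (m) is only reachable through the intermembrane
#: space (i).
_COMPARTMENT_ORDER = ["e", "c", "n", "r", "g", "l", "x", "i", "m"]

_CARBON = {"C": 6, "H": 12, "O": 6}
_PO3 = {"P": 1, "O": 3}
_ADP_FORMULA = {"C": 10, "H": 15, "N": 5, "O": 10, "P": 2}
_ATP_FORMULA = {"C": 10, "H": 15, "N": 5, "O": 13, "P": 3}


@dataclass(frozen=True)
class GenSpec:
    """Parameters of a generated model."""

    n_compartments: int = 4  # 2..9, drawn in _COMPARTMENT_ORDER
    n_uptakes: int = 3  # nutrient exchange reactions
    chain_length: int = 3  # backbone steps per pathway
    n_extra_reactions: int = 4  # random intra-compartment reactions
    fraction_reversible: float = 0.3  # of backbone metabolic steps
    with_currency: bool = True  # wire an ATP/ADP/Pi coupling
    with_blocked_branch: bool = True  # plant an unreachable dead end
    seed: int = 0

    def __post_init__(self) -> None:
        if not (2 <= self.n_compartments <= 9):
            raise ValueError("n_compartments must be between 2 and 9")
        if self.n_uptakes < 1:
            raise ValueError("a model with a biomass reaction needs at least one uptake")
        if self.chain_length < 1:
            raise ValueError("chain_length must be positive")


@dataclass
class GroundTruth:
    """What the generator knows about the model it built."""

    planted_transporters: list[CandidateTransporter] = field(default_factory=list)
    reachable: dict[str, bool] = field(default_factory=dict)  # met id -> from uptakes
    unique_compartment: dict[str, set[str]] = field(default_factory=dict)
    essential_by_target: dict[str, set[str]] = field(default_factory=dict)
    backbone_transporters: list[str] = field(default_factory=list)  # reaction ids


def generate(spec: GenSpec) -> tuple[Model, GroundTruth]:
    """Build a feasible model plus its ground truth.  Same seed, same model."""
    rng = np.random.default_rng(spec.seed)
    comps = list(_COMPARTMENT_ORDER[: spec.n_compartments])
    model = Model(id=f"syngen_seed{spec.seed}")
    for cid in comps:
        model.add_compartment(cid)
    model.default_topology()
    model.default_interfaces()
    model.notes["generator_seed"] = str(spec.seed)

    truth = GroundTruth()
    intracellular = [c for c in comps if c != "e"]
    # target compartments for the precursor pathways: cycle over organelles
    # so the biomass draws on >= 2 compartments whenever the model has them
    targets = [intracellular[k % len(intracellular)] for k in range(spec.n_uptakes)]
    if len(intracellular) >= 2 and len(set(targets)) < 2:
        targets[-1] = intracellular[1]

    biomass_stoich: dict[str, Fraction] = {}
    for k in range(spec.n_uptakes):
        prec_mid = _build_pathway(model, truth, spec, rng, k, targets[k])
        biomass_stoich[prec_mid] = Fraction(-1)

    if spec.with_currency:
        _wire_currency(model, rng, spec)

    if spec.with_blocked_branch:
        _plant_blocked_branch(model, truth)

    _add_extra_reactions(model, truth, rng, spec)

    bio = Reaction(
        id="BIOMASS",
        stoichiometry=biomass_stoich,
        reversible=False,
        lower_bound=0.0,
        upper_bound=DEFAULT_BOUND,
        rtype="biomass",
    )
    model.add_reaction(bio)
    model.biomass_reaction_id = "BIOMASS"

    for comp, bases in _unique_footprints(model).items():
        truth.unique_compartment.setdefault(comp, set()).update(bases)
    return model, truth


def _topology_path(model: Model, start: str, goal: str) -> list[str]:
    """Shortest compartment path along the adjacency topology (BFS)."""
    if start == goal:
        return [start]
    frontier = [[start]]
    seen = {start}
    while frontier:
        path = frontier.pop(0)
        for edge in sorted(model.topology, key=sorted):
            if path[-1] in edge:
                (nxt,) = edge - {path[-1]}
                if nxt in seen:
                    continue
                if nxt == goal:
                    return path + [nxt]
                seen.add(nxt)
                frontier.append(path + [nxt])
    raise ValueError(f"no topology path from {start} to {goal}")


def _add_transporter(
    model: Model, truth: GroundTruth, base: str, frm: str, to: str
) -> str:
    rid = f"T_{base}_{frm}_{to}"
    for comp in (frm, to):
        if met_id(base, comp) not in model.metabolites:
            tmpl = next(m for m in model.metabolites.values() if m.base_id == base)
            model.add_metabolite(base, comp, formula=tmpl.formula, charge=tmpl.charge)
    model.add_reaction(
        Reaction(
            id=rid,
            stoichiometry={met_id(base, frm): Fraction(-1), met_id(base, to): Fraction(1)},
            reversible=False,
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            rtype="transport",
        )
    )
    truth.backbone_transporters.append(rid)
    return rid


def _build_pathway(
    model: Model,
    truth: GroundTruth,
    spec: GenSpec,
    rng: np.random.Generator,
    k: int,
    target_comp: str,
) -> str:
    """Nutrient k: exchange -> transporters along topology -> chain -> precursor."""
    nut = f"nut{k}"
    model.add_metabolite(nut, "e", formula=dict(_CARBON), charge=0)
    model.add_reaction(
        Reaction(
            id=f"EX_{nut}_e",
            stoichiometry={met_id(nut, "e"): Fraction(-1)},
            reversible=True,
            lower_bound=-DEFAULT_BOUND,
            upper_bound=DEFAULT_BOUND,
            rtype="exchange",
        )
    )
    path = _topology_path(model, "e", target_comp)
    for frm, to in zip(path, path[1:]):
        _add_transporter(model, truth, nut, frm, to)
    # linear chain inside the target compartment ending in the precursor
    prev = nut
    essential_chain = [f"T_{nut}_{frm}_{to}" for frm, to in zip(path, path[1:])]
    for step in range(spec.chain_length):
        cur = f"prec{k}" if step == spec.chain_length - 1 else f"m{k}_{step}"
        model.add_metabolite(cur, target_comp, formula=dict(_CARBON), charge=0)
        reversible = bool(rng.random() < spec.fraction_reversible)
        rid = f"R_{k}_{step}_{target_comp}"
        model.add_reaction(
            Reaction(
                id=rid,
                stoichiometry={
                    met_id(prev, target_comp): Fraction(-1),
                    met_id(cur, target_comp): Fraction(1),
                },
                reversible=reversible,
                lower_bound=-DEFAULT_BOUND if reversible else 0.0,
                upper_bound=DEFAULT_BOUND,
                rtype="metabolic",
                gpr=f"gene_{k}_{step}",
            )
        )
        model.gene_products.setdefault(
            f"gene_{k}_{step}",
            GeneProduct(id=f"gene_{k}_{step}", symbol=f"g{k}.{step}", compartment=target_comp),
        )
        essential_chain.append(rid)
        prev = cur
    prec_mid = met_id(f"prec{k}", target_comp)
    truth.essential_by_target[prec_mid] = set(essential_chain) | {f"EX_{nut}_e"}
    # everything on the backbone is reachable from uptakes
    truth.reachable[met_id(nut, "e")] = True
    for comp in path[1:]:
        truth.reachable[met_id(nut, comp)] = True
    for step in range(spec.chain_length):
        cur = f"prec{k}" if step == spec.chain_length - 1 else f"m{k}_{step}"
        truth.reachable[met_id(cur, target_comp)] = True
    return prec_mid


def _wire_currency(model: Model, rng: np.random.Generator, spec: GenSpec) -> None:
    """ATP-coupled step plus a regeneration loop, mass-balanced throughout."""
    for base, formula, charge in (
        ("atp", _ATP_FORMULA, -4),
        ("adp", _ADP_FORMULA, -3),
        ("pi", _PO3, -2),
    ):
        model.add_metabolite(base, "c", formula=formula, charge=charge)
    # couple ATP hydrolysis to the first cytosolic-passing nutrient transporter
    # by adding a parallel driven reaction: nut0[c] + atp -> act0[c] + adp + pi
    if met_id("nut0", "c") in model.metabolites:
        model.add_metabolite("act0", "c", formula=dict(_CARBON), charge=0)
        model.add_reaction(
            Reaction(
                id="R_atp_coupled",
                stoichiometry={
                    met_id("nut0", "c"): Fraction(-1),
                    met_id("atp", "c"): Fraction(-1),
                    met_id("act0", "c"): Fraction(1),
                    met_id("adp", "c"): Fraction(1),
                    met_id("pi", "c"): Fraction(1),
                },
                reversible=False,
                rtype="metabolic",
            )
        )
        # sink so the coupled branch can actually run
        model.add_reaction(
            Reaction(
                id="R_act0_drain",
                stoichiometry={
                    met_id("act0", "c"): Fraction(-1),
                    met_id("nut0", "c"): Fraction(1),
                },
                reversible=False,
                rtype="metabolic",
            )
        )
    model.add_reaction(
        Reaction(
            id="R_atp_regen",
            stoichiometry={
                met_id("adp", "c"): Fraction(-1),
                met_id("pi", "c"): Fraction(-1),
                met_id("atp", "c"): Fraction(1),
            },
            reversible=False,
            rtype="metabolic",
        )
    )


def _plant_blocked_branch(model: Model, truth: GroundTruth) -> None:
    """A dead-end pair: dead0 has no producer, so dead1 is unreachable."""
    model.add_metabolite("dead0", "c", formula=dict(_CARBON), charge=0)
    model.add_metabolite("dead1", "c", formula=dict(_CARBON), charge=0)
    model.add_reaction(
        Reaction(
            id="R_blocked",
            stoichiometry={
                met_id("dead0", "c"): Fraction(-1),
                met_id("dead1", "c"): Fraction(1),
            },
            reversible=False,
            rtype="metabolic",
        )
    )
    truth.reachable[met_id("dead0", "c")] = False
    truth.reachable[met_id("dead1", "c")] = False


def _add_extra_reactions(
    model: Model, truth: GroundTruth, rng: np.random.Generator, spec: GenSpec
) -> None:
    """Random intra-compartment side branches off backbone metabolites.

    Each extra converts a backbone species into a fresh side product within
    the same compartment.  Side branches keep the backbone transporters
    unique as inter-compartment routes and never bypass a backbone step, so
    the recorded essentiality and gap ground truth stays exact; side
    products are still synthesisable (a demand probe can pull them), which
    exercises reachability analysis.
    """
    pool = sorted(
        m.id
        for m in model.metabolites.values()
        if m.base_id.startswith(("m", "nut", "prec")) and m.compartment != "e"
    )
    for j in range(spec.n_extra_reactions):
        if not pool:
            return
        src = pool[int(rng.integers(len(pool)))]
        comp = model.metabolites[src].compartment
        side = f"side{j}"
        model.add_metabolite(side, comp, formula=dict(_CARBON), charge=0)
        model.add_reaction(
            Reaction(
                id=f"X_{j}_{comp}",
                stoichiometry={src: Fraction(-1), met_id(side, comp): Fraction(1)},
                reversible=False,
                rtype="metabolic",
            )
        )
        truth.reachable[met_id(side, comp)] = bool(truth.reachable.get(src, False))


def _unique_footprints(model: Model) -> dict[str, set[str]]:
    """Compartment-unique identities from the generator's own records."""
    placements: dict[str, set[str]] = {}
    for met in model.metabolites.values():
        if met.base_id in model.currency_list:
            continue
        placements.setdefault(met.base_id, set()).add(met.compartment)
    out: dict[str, set[str]] = {}
    for base, comps in placements.items():
        if len(comps) == 1:
            (comp,) = comps
            out.setdefault(comp, set()).add(base)
    return out


def plant_gaps(
    model: Model, k: int, seed: int = 0
) -> tuple[Model, list[CandidateTransporter]]:
    """Remove ``k`` transporters whose loss each breaks biomass production.

    Returns the gapped model and the removed transporters as candidate
    records (the ground truth a gap filler should recover).  ``k = 0``
    returns an unchanged copy.
    """
    from .fba import can_carry_flux

    if k == 0:
        return model.copy(), []
    if not can_carry_flux(model, model.biomass_reaction_id, "forward", 1.0)[0]:
        raise ValueError("model must be biomass-feasible before planting gaps")
    rng = np.random.default_rng(seed)
    transporters = sorted(
        rid for rid, r in model.reactions.items() if r.rtype == "transport"
    )
    breaking: list[str] = []
    for rid in transporters:
        probe = model.copy()
        probe.reactions[rid].lower_bound = 0.0
        probe.reactions[rid].upper_bound = 0.0
        if not can_carry_flux(probe, model.biomass_reaction_id, "forward", 1.0)[0]:
            breaking.append(rid)
    if len(breaking) < k:
        raise ValueError(
            f"only {len(breaking)} transporters individually break biomass; need {k}"
        )
    chosen = sorted(rng.choice(breaking, size=k, replace=False).tolist())
    gapped = model.copy()
    removed: list[CandidateTransporter] = []
    for rid in chosen:
        rxn = gapped.reactions.pop(rid)
        (src,) = [m for m, c in rxn.stoichiometry.items() if c < 0]
        (dst,) = [m for m, c in rxn.stoichiometry.items() if c > 0]
        removed.append(
            CandidateTransporter(
                base_id=gapped.metabolites[src].base_id,
                from_compartment=gapped.metabolites[src].compartment,
                to_compartment=gapped.metabolites[dst].compartment,
                reversible=rxn.reversible,
            )
        )
    return gapped, removed
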
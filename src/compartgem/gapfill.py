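"""Cardinality-minimal transporter gap filling.

A compartmentalised draft model often cannot synthesise biomass because a
metabolite is produced in one compartment and needed in another with no
transporter connecting them.  Gap filling searches for the minimal number of
transport reactions, drawn from candidates along the physical compartment
topology, whose addition restores biomass production.

Minimality is certified with a mixed-integer linear program: a binary
indicator per candidate gates its flux bounds, and the indicator sum is
minimised subject to steady state and a biomass flux requirement.  Among
equal-cardinality optima, ties are broken deterministically by preferring
candidates that pass both manual-curation criteria, then lexicographic id;
the tie-break is implemented as a tiny secondary cost that can never change
the optimal cardinality.

Each accepted transporter is audited against two curation criteria:

(i)  the addition must not amount to making a known irreversible transporter
     reversible (no reversible duplicate of an existing irreversible
     transporter in the opposite direction);
(ii) the transporter should carry the metabolite from a compartment where
     some reaction produces it to a compartment where some reaction consumes
     it as a reactant.

Failing a criterion never deletes the transporter — it flags it for review.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from fractions import Fraction
from typing import Iterable, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import LinearConstraint, Bounds, milp

from .constants import DEFAULT_BOUND
from .fba import build_system
from .model import Model, Reaction, met_id


@dataclass(frozen=True)
class CandidateTransporter:
    """A potential transport reaction: one metabolite, one topology edge."""

    base_id: str
    from_compartment: str
    to_compartment: str
    reversible: bool = False
    provenance: str = "generated"  # or "user_supplied"

    @property
    def id(self) -> str:
        return f"GT_{self.base_id}_{self.from_compartment}_{self.to_compartment}"

    def to_reaction(self, bound: float = DEFAULT_BOUND) -> Reaction:
        return Reaction(
            id=self.id,
            stoichiometry={
                met_id(self.base_id, self.from_compartment): Fraction(-1),
                met_id(self.base_id, self.to_compartment): Fraction(1),
            },
            reversible=self.reversible,
            lower_bound=-bound if self.reversible else 0.0,
            upper_bound=bound,
            rtype="transport",
        )


@dataclass
class GapFillResult:
    status: str  # already_feasible | filled | unfillable
    added: list[CandidateTransporter] = field(default_factory=list)
    audit: dict[str, dict[str, bool]] = field(default_factory=dict)
    message: str = ""

    @property
    def cardinality(self) -> int:
        return len(self.added)


def enumerate_candidates(model: Model) -> list[CandidateTransporter]:
    """All (metabolite, topology edge, direction) transport candidates.

    A candidate is emitted when the metabolite already exists in at least one
    of the edge's two compartments; the missing species is instantiated on
    demand when the transporter is applied.  Currency metabolites are
    included — cofactor transport gaps are real gaps.
    """
    if not model.topology:
        raise ValueError("model has no compartment topology")
    bases_by_comp: dict[str, set[str]] = {}
    for met in model.metabolites.values():
        bases_by_comp.setdefault(met.compartment, set()).add(met.base_id)
    seen: set[tuple[str, str, str]] = set()
    out: list[CandidateTransporter] = []
    for edge in sorted(model.topology, key=sorted):
        a, b = sorted(edge)
        bases = bases_by_comp.get(a, set()) | bases_by_comp.get(b, set())
        for base in sorted(bases):
            for frm, to in ((a, b), (b, a)):
                key = (base, frm, to)
                if key not in seen:
                    seen.add(key)
                    out.append(CandidateTransporter(base, frm, to))
    return out


def apply_candidates(
    model: Model, candidates: Iterable[CandidateTransporter]
) -> Model:
    """Return a copy of the model with the candidate transporters added."""
    augmented = model.copy()
    for cand in candidates:
        for comp in (cand.from_compartment, cand.to_compartment):
            mid = met_id(cand.base_id, comp)
            if mid not in augmented.metabolites:
                template = next(
                    (
                        m
                        for m in augmented.metabolites.values()
                        if m.base_id == cand.base_id
                    ),
                    None,
                )
                augmented.add_metabolite(
                    cand.base_id,
                    comp,
                    formula=template.formula if template else None,
                    charge=template.charge if template else None,
                )
        augmented.add_reaction(cand.to_reaction())
    return augmented


def _biomass_feasible(model: Model, biomass_threshold: float) -> bool:
    from .fba import can_carry_flux

    ok, _ = can_carry_flux(model, model.biomass_reaction_id, "forward", biomass_threshold)
    return ok


def gap_fill(
    model: Model,
    candidates: Sequence[CandidateTransporter] | None = None,
    max_cardinality: int = 20,
    biomass_threshold: float = 1.0,
    bound: float = DEFAULT_BOUND,
    audit: bool = True,
) -> GapFillResult:
    """Find a provably minimum-cardinality transporter set enabling biomass.

    Parameters
    ----------
    model
        The (possibly infeasible) compartmentalised model.
    candidates
        Candidate transporters; defaults to :func:`enumerate_candidates`.
    max_cardinality
        Upper bound on the number of additions (bounds the MILP).
    biomass_threshold
        Minimum biomass flux the augmented model must sustain.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    if _biomass_feasible(model, biomass_threshold):
        return GapFillResult(status="already_feasible")
    if candidates is None:
        candidates = enumerate_candidates(model)
    if not candidates:
        return GapFillResult(status="unfillable", message="no candidates supplied")

    candidates = sorted(candidates, key=lambda c: c.id)
    augmented = apply_candidates(model, candidates)
    system = build_system(augmented)
    n = system.n_reactions
    k = len(candidates)
    cand_cols = np.array([system.rxn_index[c.id] for c in candidates])

    # Secondary cost: prefer audit-passing candidates, then lexicographic id.
    # delta < 1/k per candidate keeps the total tie-break weight below 1, so
    # the optimal indicator sum (cardinality) is untouched.
    flags = _audit_candidates(model, candidates)
    delta = np.zeros(k)
    for j, cand in enumerate(candidates):
        f = flags[cand.id]
        penalty = (0 if f["criterion_i"] else 1) + (0 if f["criterion_ii"] else 1)
        delta[j] = (penalty * 1e-3 + j * 1e-7) / max(k, 1)

    # variables: v (n continuous) then y (k binary)
    c = np.concatenate([np.zeros(n), np.ones(k) + delta])
    integrality = np.concatenate([np.zeros(n), np.ones(k)])
    lower = system.lower.copy()
    upper = system.upper.copy()
    bio_idx = system.rxn_index[model.biomass_reaction_id]
    lower[bio_idx] = max(lower[bio_idx], biomass_threshold)
    # candidate columns are free only when selected: 0 <= v_j <= M y_j
    lower[cand_cols] = 0.0
    constraints = [
        LinearConstraint(
            sparse.hstack([system.S, sparse.csr_matrix((system.n_metabolites, k))]),
            0.0,
            0.0,
        )
    ]
    rows, cols, vals = [], [], []
    for j, col in enumerate(cand_cols):
        rows.append(j)
        cols.append(int(col))
        vals.append(1.0)
        rows.append(j)
        cols.append(n + j)
        vals.append(-bound)
    A_gate = sparse.csr_matrix((vals, (rows, cols)), shape=(k, n + k))
    constraints.append(LinearConstraint(A_gate, -np.inf, 0.0))
    card_row = sparse.csr_matrix(
        (np.ones(k), (np.zeros(k, dtype=int), n + np.arange(k))), shape=(1, n + k)
    )
    constraints.append(LinearConstraint(card_row, 0, float(max_cardinality)))
    var_bounds = Bounds(
        np.concatenate([lower, np.zeros(k)]), np.concatenate([upper, np.ones(k)])
    )
    res = milp(
        c=c,
        constraints=constraints,
        integrality=integrality,
        bounds=var_bounds,
        options={"mip_rel_gap": 0.0},
    )
    if res.status == 2:  # infeasible
        return GapFillResult(
            status="unfillable",
            message=f"no subset of <= {max_cardinality} candidates restores biomass",
        )
    if res.status != 0 or res.x is None:
        raise RuntimeError(f"MILP solver failed: {res.message}")
    chosen = [candidates[j] for j in range(k) if res.x[n + j] > 0.5]
    result = GapFillResult(status="filled", added=chosen)
    if audit:
        result = audit_result(model, result)
    return result


def _producers_consumers(model: Model, base_id: str) -> tuple[set[str], set[str]]:
    """Compartments where some reaction produces / consumes the metabolite.

    A reversible reaction both produces and consumes everything it touches.
    An exchange reaction able to run as an uptake counts as production in the
    extracellular compartment (the nutrient is available there); demand sinks
    are not evidence of anything.
    """
    produced: set[str] = set()
    consumed: set[str] = set()
    for rxn in model.reactions.values():
        if rxn.rtype == "demand":
            continue
        for mid, coeff in rxn.stoichiometry.items():
            met = model.metabolites[mid]
            if met.base_id != base_id:
                continue
            if coeff > 0 or rxn.reversible:
                produced.add(met.compartment)
            if coeff < 0 or rxn.reversible:
                consumed.add(met.compartment)
    return produced, consumed


def _audit_candidates(
    model: Model, candidates: Sequence[CandidateTransporter]
) -> dict[str, dict[str, bool]]:
    flags: dict[str, dict[str, bool]] = {}
    # existing irreversible transporters of a base over an edge, by direction
    irreversible: set[tuple[str, str, str]] = set()
    for rxn in model.reactions.values():
        if rxn.rtype != "transport" or rxn.reversible:
            continue
        for src_mid, src_coeff in rxn.stoichiometry.items():
            if src_coeff >= 0:
                continue
            src = model.metabolites[src_mid]
            for dst_mid, dst_coeff in rxn.stoichiometry.items():
                if dst_coeff <= 0:
                    continue
                dst = model.metabolites[dst_mid]
                if src.base_id == dst.base_id and src.compartment != dst.compartment:
                    irreversible.add((src.base_id, src.compartment, dst.compartment))
    for cand in candidates:
        reverses = (
            cand.base_id,
            cand.to_compartment,
            cand.from_compartment,
        ) in irreversible
        produced, consumed = _producers_consumers(model, cand.base_id)
        flags[cand.id] = {
            # criterion (i): adding this direction must not undo a known
            # irreversibility (the pair would act as a reversible carrier)
            "criterion_i": not reverses,
            # criterion (ii): producer-side origin, consumer-side destination
            "criterion_ii": (
                cand.from_compartment in produced and cand.to_compartment in consumed
            ),
        }
    return flags


def audit_result(model: Model, result: GapFillResult) -> GapFillResult:
    """Attach the two manual-curation criterion flags to a filled result."""
    if result.status != "filled":
        raise ValueError("audit is only defined for a filled result")
    flags = _audit_candidates(model, result.added)
    return replace(result, audit={c.id: flags[c.id] for c in result.added})
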
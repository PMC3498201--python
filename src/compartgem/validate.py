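"""Functional-validation simulations: can a target be made from a source?

Each validation case asks whether a target metabolite can be synthesised at
steady state from a stated set of source nutrients without touching any
internal reaction constraint.  The test model is built by

1. closing the uptake direction of every exchange reaction except the case's
   sources and the freely exchanged species (oxygen, water, carbon dioxide),
2. opening any extra exchange reactions the case declares,
3. adding a demand sink consuming the target in its own compartment,

and then asking whether the demand can carry flux.  Only uptake availability
is manipulated; all non-exchange bounds are untouched.

Essential reactions for a passing case are found by single deletion: a
reaction is essential iff zeroing its bounds turns the case into a failure.
The fast scan only deletes reactions active in a passing witness — a
reaction idle in some feasible witness can never be essential, so the fast
scan is exact, not a heuristic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Sequence

from .constants import DEFAULT_BOUND, EPSILON, FREE_EXCHANGE
from .fba import can_carry_flux
from .model import Model, Reaction, met_id, split_met_id


@dataclass(frozen=True)
class ValidationCase:
    """One source -> target synthesis test."""

    id: str
    sources: tuple[str, ...]  # metabolite ids (base[comp]) allowed as inputs
    target: str  # metabolite id (base[comp]) to synthesise
    extra_exchanges: tuple[str, ...] = ()  # exchange reaction ids to open
    expected: str = "pass"  # or "fail"


@dataclass(frozen=True)
class CaseResult:
    case_id: str
    status: str  # pass | fail | error
    expected: str
    witness_objective: float | None = None
    message: str = ""

    @property
    def as_expected(self) -> bool:
        return self.status == self.expected


@dataclass
class SuiteReport:
    results: list[CaseResult] = field(default_factory=list)

    @property
    def n_passed(self) -> int:
        return sum(1 for r in self.results if r.status == "pass")

    @property
    def n_failed(self) -> int:
        return sum(1 for r in self.results if r.status == "fail")

    @property
    def n_errored(self) -> int:
        return sum(1 for r in self.results if r.status == "error")

    def to_records(self) -> list[dict]:
        return [
            {
                "id": r.case_id,
                "status": r.status,
                "expected": r.expected,
                "as_expected": r.as_expected,
                "message": r.message,
            }
            for r in self.results
        ]


_DEMAND_ID = "DM_validation_target"


def _build_test_model(
    model: Model,
    case: ValidationCase,
    free_exchange: Iterable[str] = FREE_EXCHANGE,
) -> Model:
    test = model.copy()
    free = frozenset(free_exchange)
    source_bases = set()
    source_mids = set()
    for src in case.sources:
        base, _ = split_met_id(src)
        source_bases.add(base)
        source_mids.add(src)
    # close all uptakes except sources and free species
    for rxn in test.reactions.values():
        if rxn.rtype != "exchange":
            continue
        (mid,) = rxn.stoichiometry
        base = test.metabolites[mid].base_id
        if base in free or base in source_bases or rxn.id in case.extra_exchanges:
            continue
        rxn.lower_bound = 0.0  # no influx; secretion stays open
        rxn.reversible = False
    # sources without an exchange are injected directly in their compartment
    has_exchange = {
        next(iter(r.stoichiometry))
        for r in test.reactions.values()
        if r.rtype == "exchange"
    }
    for src in sorted(source_mids):
        if src in has_exchange:
            continue
        if src not in test.metabolites:
            raise KeyError(f"case {case.id}: unknown source metabolite {src!r}")
        sid = f"SRC_{split_met_id(src)[0]}_{split_met_id(src)[1]}"
        test.add_reaction(
            Reaction(
                id=sid,
                stoichiometry={src: Fraction(1)},
                reversible=False,
                lower_bound=0.0,
                upper_bound=DEFAULT_BOUND,
                rtype="demand",
            )
        )
    test.add_reaction(
        Reaction(
            id=_DEMAND_ID,
            stoichiometry={case.target: Fraction(-1)},
            reversible=False,
            lower_bound=0.0,
            upper_bound=DEFAULT_BOUND,
            rtype="demand",
        )
    )
    return test


def simulate_function(
    model: Model,
    case: ValidationCase,
    epsilon: float = EPSILON,
    free_exchange: Iterable[str] = FREE_EXCHANGE,
) -> CaseResult:
    """Run one synthesis test; returns pass/fail with a witness objective."""
    if case.target not in model.metabolites:
        return CaseResult(
            case_id=case.id,
            status="error",
            expected=case.expected,
            message=f"target metabolite {case.target!r} not in model",
        )
    try:
        test = _build_test_model(model, case, free_exchange)
    except KeyError as exc:
        return CaseResult(
            case_id=case.id, status="error", expected=case.expected, message=str(exc)
        )
    ok, witness = can_carry_flux(test, _DEMAND_ID, "forward", epsilon)
    return CaseResult(
        case_id=case.id,
        status="pass" if ok else "fail",
        expected=case.expected,
        witness_objective=(witness.fluxes[_DEMAND_ID] if ok else None),
    )


def run_suite(
    model: Model,
    cases: Sequence[ValidationCase],
    epsilon: float = EPSILON,
    free_exchange: Iterable[str] = FREE_EXCHANGE,
) -> SuiteReport:
    """Evaluate every case independently; per-case errors never abort."""
    if not cases:
        raise ValueError("suite requires at least one case")
    report = SuiteReport()
    for case in cases:
        try:
            report.results.append(simulate_function(model, case, epsilon, free_exchange))
        except Exception as exc:  # pragma: no cover - defensive
            report.results.append(
                CaseResult(
                    case_id=case.id,
                    status="error",
                    expected=case.expected,
                    message=f"{type(exc).__name__}: {exc}",
                )
            )
    return report


def essential_reactions_for_target(
    model: Model,
    case: ValidationCase,
    exhaustive: bool = False,
    epsilon: float = EPSILON,
) -> set[str]:
    """Reactions whose single deletion breaks the case.

    ``exhaustive=True`` scans every reaction instead of only those carrying
    flux in a witness; both scans return the same set (a reaction idle in a
    feasible witness cannot be essential), so the flag exists for auditing.
    """
    test = _build_test_model(model, case)
    ok, witness = can_carry_flux(test, _DEMAND_ID, "forward", epsilon)
    if not ok:
        raise ValueError(f"case {case.id} fails on the full model; essentiality undefined")
    if exhaustive:
        scan = [r for r in model.reactions]
    else:
        scan = [
            rid
            for rid, flux in witness.fluxes.items()
            if rid in model.reactions and abs(flux) >= epsilon
        ]
    essential: set[str] = set()
    for rid in sorted(scan):
        if rid == _DEMAND_ID:
            continue
        knocked = test.copy()
        rxn = knocked.reactions[rid]
        rxn.lower_bound = 0.0
        rxn.upper_bound = 0.0
        still_ok, _ = can_carry_flux(knocked, _DEMAND_ID, "forward", epsilon)
        if not still_ok:
            essential.add(rid)
    return essential
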
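"""Steady-state flux balance analysis with a minimise-uptake objective.

The steady state assumption is ``S v = 0`` with ``S`` the metabolites ×
reactions stoichiometric matrix and ``v`` the flux vector, bounded per
reaction.  The optimum flux distribution is the one that minimises total
nutrient uptake at a fixed rate of biomass synthesis.  Exchange fluxes are
negative for influx and positive for efflux, so only the negative part of
each exchange flux enters the objective; this is linearised with one
auxiliary variable per exchange reaction (``u_j >= -v_j``, ``u_j >= 0``,
minimise ``sum u_j``).  Species on the free-exchange list (oxygen, water,
carbon dioxide by default) are excluded from the objective.

Currency metabolites are never removed here: cofactor balancing is part of
the flux problem even though the cofactors are pruned from graph analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .constants import DEFAULT_BIOMASS_RATE, EPSILON, FREE_EXCHANGE
from .model import Model


@dataclass
class StoichiometricSystem:
    """The model's stoichiometry as a sparse matrix plus index maps."""

    S: sparse.csr_matrix  # metabolites x reactions
    lower: np.ndarray
    upper: np.ndarray
    met_index: dict[str, int]
    rxn_index: dict[str, int]
    rxn_ids: list[str]

    @property
    def n_reactions(self) -> int:
        return self.S.shape[1]

    @property
    def n_metabolites(self) -> int:
        return self.S.shape[0]


@dataclass
class FluxState:
    """A solved flux distribution."""

    status: str  # optimal | infeasible | unbounded | error
    fluxes: dict[str, float] = field(default_factory=dict)
    objective_value: float | None = None
    message: str = ""

    @property
    def optimal(self) -> bool:
        return self.status == "optimal"


def build_system(model: Model) -> StoichiometricSystem:
    """Assemble ``S`` with one column per reaction, exchanges included.

    Reversible reactions keep their signed bounds; no splitting happens at
    this layer.
    """
    met_ids = sorted(model.metabolites)
    rxn_ids = sorted(model.reactions)
    met_index = {m: i for i, m in enumerate(met_ids)}
    rxn_index = {r: j for j, r in enumerate(rxn_ids)}
    rows, cols, vals = [], [], []
    for rid in rxn_ids:
        j = rxn_index[rid]
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            rows.append(met_index[mid])
            cols.append(j)
            vals.append(float(coeff))
    S = sparse.csr_matrix(
        (vals, (rows, cols)), shape=(len(met_ids), len(rxn_ids))
    )
    lower = np.array([model.reactions[r].lower_bound for r in rxn_ids], dtype=float)
    upper = np.array([model.reactions[r].upper_bound for r in rxn_ids], dtype=float)
    return StoichiometricSystem(S, lower, upper, met_index, rxn_index, rxn_ids)


_STATUS = {0: "optimal", 1: "error", 2: "infeasible", 3: "unbounded", 4: "error"}


def _solve_lp(
    system: StoichiometricSystem,
    c: np.ndarray,
    extra_lower: Mapping[int, float] | None = None,
    extra_upper: Mapping[int, float] | None = None,
    fixed: Mapping[int, float] | None = None,
    n_aux: int = 0,
    aux_rows: sparse.spmatrix | None = None,
    aux_rhs: np.ndarray | None = None,
) -> tuple[str, np.ndarray | None, float | None, str]:
    """Solve min c.x s.t. [S 0] x = 0, optional A_ub x <= b, bounds."""
    n = system.n_reactions
    lower = system.lower.copy()
    upper = system.upper.copy()
    for idx, val in (extra_lower or {}).items():
        lower[idx] = max(lower[idx], val)
    for idx, val in (extra_upper or {}).items():
        upper[idx] = min(upper[idx], val)
    for idx, val in (fixed or {}).items():
        lower[idx] = upper[idx] = val
    if n_aux:
        A_eq = sparse.hstack(
            [system.S, sparse.csr_matrix((system.n_metabolites, n_aux))], format="csr"
        )
        bounds_lo = np.concatenate([lower, np.zeros(n_aux)])
        bounds_hi = np.concatenate([upper, np.full(n_aux, np.inf)])
    else:
        A_eq = system.S
        bounds_lo, bounds_hi = lower, upper
    res = linprog(
        c,
        A_ub=aux_rows,
        b_ub=aux_rhs,
        A_eq=A_eq,
        b_eq=np.zeros(system.n_metabolites),
        bounds=np.column_stack([bounds_lo, bounds_hi]),
        method="highs",
    )
    status = _STATUS.get(res.status, "error")
    if status == "optimal":
        return status, res.x, float(res.fun), res.message
    return status, None, None, res.message


def solve_min_uptake(
    model: Model,
    biomass_rate: float = DEFAULT_BIOMASS_RATE,
    free_exchange: Iterable[str] = FREE_EXCHANGE,
) -> FluxState:
    """Minimise total uptake at a fixed biomass synthesis rate.

    Parameters
    ----------
    model
        Model with a biomass reaction and at least one exchange reaction.
    biomass_rate
        The biomass flux is fixed to this value with an equality constraint.
    free_exchange
        Base ids of species whose exchange flux does not count as uptake.

    Returns
    -------
    FluxState with status ``optimal`` (objective = total uptake flux),
    ``infeasible`` (the rate cannot be sustained) or ``unbounded``.
    """
    if model.biomass_reaction_id is None:
        raise ValueError("model has no biomass reaction")
    exchanges = model.exchange_reactions()
    if not exchanges:
        raise ValueError("model has no exchange reactions")
    free = frozenset(free_exchange)
    system = build_system(model)
    n = system.n_reactions
    costed = [
        r for r in exchanges
        if model.metabolites[next(iter(r.stoichiometry))].base_id not in free
    ]
    k = len(costed)
    # variables: v (n) then u (k); u_j >= -v_j  <=>  -v_j - u_j <= 0
    c = np.concatenate([np.zeros(n), np.ones(k)])
    rows, cols, vals = [], [], []
    for a, rxn in enumerate(costed):
        rows.append(a)
        cols.append(system.rxn_index[rxn.id])
        vals.append(-1.0)
        rows.append(a)
        cols.append(n + a)
        vals.append(-1.0)
    A_ub = sparse.csr_matrix((vals, (rows, cols)), shape=(k, n + k)) if k else None
    b_ub = np.zeros(k) if k else None
    bio_idx = system.rxn_index[model.biomass_reaction_id]
    status, x, fun, message = _solve_lp(
        system,
        c,
        fixed={bio_idx: biomass_rate},
        n_aux=k,
        aux_rows=A_ub,
        aux_rhs=b_ub,
    )
    if status != "optimal":
        note = message
        if status == "infeasible":
            note = f"infeasible at biomass_rate={biomass_rate}: {message}"
        return FluxState(status=status, message=note)
    fluxes = {rid: float(x[j]) for rid, j in system.rxn_index.items()}
    return FluxState(status="optimal", fluxes=fluxes, objective_value=fun, message=message)


def can_carry_flux(
    model: Model,
    reaction_id: str,
    direction: str = "forward",
    epsilon: float = EPSILON,
) -> tuple[bool, FluxState | None]:
    """Can the reaction carry at least ``epsilon`` flux in a steady state?

    Returns ``(True, witness)`` where the witness is a feasible flux
    distribution with the requested flux, or ``(False, None)``.
    """
    if reaction_id not in model.reactions:
        raise KeyError(f"unknown reaction {reaction_id!r}")
    if direction not in ("forward", "reverse"):
        raise ValueError(f"direction must be forward or reverse, got {direction!r}")
    system = build_system(model)
    idx = system.rxn_index[reaction_id]
    c = np.zeros(system.n_reactions)
    if direction == "forward":
        status, x, _, _ = _solve_lp(system, c, extra_lower={idx: epsilon})
    else:
        status, x, _, _ = _solve_lp(system, c, extra_upper={idx: -epsilon})
    if status != "optimal":
        return False, None
    fluxes = {rid: float(x[j]) for rid, j in system.rxn_index.items()}
    return True, FluxState(status="optimal", fluxes=fluxes, objective_value=0.0)


def residual(system: StoichiometricSystem, state: FluxState) -> float:
    """Max-norm of ``S v`` for a solved state (steady-state violation)."""
    v = np.array([state.fluxes[r] for r in system.rxn_ids])
    return float(np.abs(system.S @ v).max()) if len(v) else 0.0
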
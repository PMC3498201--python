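"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the code paths they verify: the LP oracle
enumerates basic feasible points of the flux polytope directly, the graph
oracle runs a dense Floyd-Warshall, and the gap-fill oracle searches subsets
exhaustively in increasing cardinality.
"""

from __future__ import annotations

import itertools

import numpy as np

from compartgem.fba import can_carry_flux
from compartgem.gapfill import apply_candidates
from compartgem.model import Model


def oracle_min_uptake(model: Model, biomass_rate: float, free=()) -> float | None:
    """Minimum total uptake by vertex enumeration (tiny networks only).

    Splits the piecewise-linear objective by orthant over the costed
    exchange fluxes; within each orthant the objective is linear, so the
    optimum lies at a basic feasible point of the equality system, which is
    enumerated directly.  Returns None if no feasible point exists.
    """
    rxn_ids = sorted(model.reactions)
    met_ids = sorted(model.metabolites)
    n = len(rxn_ids)
    S = np.zeros((len(met_ids), n))
    for j, rid in enumerate(rxn_ids):
        for mid, coeff in model.reactions[rid].stoichiometry.items():
            S[met_ids.index(mid), j] = float(coeff)
    lb = np.array([model.reactions[r].lower_bound for r in rxn_ids], float)
    ub = np.array([model.reactions[r].upper_bound for r in rxn_ids], float)
    bio = rxn_ids.index(model.biomass_reaction_id)
    lb[bio] = ub[bio] = biomass_rate
    costed = [
        j
        for j, rid in enumerate(rxn_ids)
        if model.reactions[rid].rtype == "exchange"
        and model.metabolites[next(iter(model.reactions[rid].stoichiometry))].base_id
        not in free
    ]
    best = None
    for signs in itertools.product((-1, 1), repeat=len(costed)):
        olb, oub = lb.copy(), ub.copy()
        cvec = np.zeros(n)
        for j, sgn in zip(costed, signs):
            if sgn < 0:
                oub[j] = min(oub[j], 0.0)
                cvec[j] = -1.0  # uptake magnitude
            else:
                olb[j] = max(olb[j], 0.0)
        val = _orthant_min(S, olb, oub, cvec)
        if val is not None and (best is None or val < best - 1e-12):
            best = val
    return best


def _orthant_min(S, lb, ub, cvec, tol=1e-7):
    m, n = S.shape
    rank = np.linalg.matrix_rank(S, tol=1e-10)
    best = None
    for free_vars in itertools.combinations(range(n), rank):
        fixed = [j for j in range(n) if j not in free_vars]
        for assignment in itertools.product((0, 1), repeat=len(fixed)):
            x = np.empty(n)
            for j, a in zip(fixed, assignment):
                x[j] = lb[j] if a == 0 else ub[j]
            A = S[:, list(free_vars)]
            b = -S[:, fixed] @ x[fixed] if fixed else np.zeros(m)
            sol, res, rk, _ = np.linalg.lstsq(A, b, rcond=None)
            x[list(free_vars)] = sol
            if np.max(np.abs(S @ x)) > tol:
                continue
            if np.any(x < lb - tol) or np.any(x > ub + tol):
                continue
            val = float(cvec @ x)
            if best is None or val < best:
                best = val
    return best


def oracle_min_gapfill_cardinality(
    model: Model, candidates, max_k: int, biomass_threshold: float = 1.0
) -> int | None:
    """Smallest candidate subset restoring biomass, by exhaustive search."""
    if can_carry_flux(model, model.biomass_reaction_id, "forward", biomass_threshold)[0]:
        return 0
    for k in range(1, max_k + 1):
        for subset in itertools.combinations(candidates, k):
            augmented = apply_candidates(model, subset)
            if can_carry_flux(
                augmented, model.biomass_reaction_id, "forward", biomass_threshold
            )[0]:
                return k
    return None


def oracle_graph_stats(graph) -> tuple[float, int, float]:
    """(density, diameter, average path length) by dense Floyd-Warshall."""
    nodes = sorted(graph.nodes)
    n = len(nodes)
    index = {v: i for i, v in enumerate(nodes)}
    INF = float("inf")
    dist = [[0 if i == j else INF for j in range(n)] for i in range(n)]
    n_edges = 0
    for u, v in graph.edges:
        if u != v:
            dist[index[u]][index[v]] = 1
            n_edges += 1
    for k in range(n):
        for i in range(n):
            for j in range(n):
                if dist[i][k] + dist[k][j] < dist[i][j]:
                    dist[i][j] = dist[i][k] + dist[k][j]
    finite = [
        dist[i][j]
        for i in range(n)
        for j in range(n)
        if i != j and dist[i][j] < INF
    ]
    dens = n_edges / (n * (n - 1))
    if not finite:
        return dens, -1, float("nan")
    return dens, max(finite), sum(finite) / len(finite)
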
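# Methods

## Model representation

A model is a set of compartments, membrane interfaces, metabolites,
reactions and gene products plus a *topology*: the unordered pairs of
compartments that physically adjoin. The default layout has nine
compartments. The extracellular space touches only the cytoplasm; every
organelle touches the cytoplasm except the mitochondrial matrix, which is
reached through the intermembrane space; vesicular routes add ER–Golgi,
Golgi–lysosome and Golgi–plasma-membrane edges. Transport candidates in gap
filling are restricted to these edges, so the topology is the physical prior
of the method.

Interfaces describe where a reaction's active site sits: one lumen interface
per compartment plus nine membrane faces (plasma membrane exofacial side,
cytosolic faces of ER/Golgi/lysosome/nucleus/peroxisome/outer mitochondrial
membrane, and both faces of the inner mitochondrial membrane), 18 in total.
The exact membrane-face list of a given reconstruction is rarely published
as data, so this default is a reconstruction from the compartment schematic
and is overridable from configuration. Orientation is metadata with one
validation rule: a non-transport membrane reaction must draw all of its
metabolites from the compartment its interface faces. It never alters
stoichiometry or the LP.

Stoichiometric coefficients are exact `Fraction`s; mass- and charge-balance
checks are therefore exact, and floats appear only when the LP matrix is
assembled. Metabolite ids follow the `base[compartment]` suffix convention
(`atp[c]`); ionisation states (pH 7.2) are treated as constant across
compartments, which the validator enforces as identical formula/charge for
equal base ids. GPRs are boolean trees over gene ids; when complex
composition is unknown, isozymes default to OR. Mass/charge checks skip
boundary pseudo-reactions (exchange, biomass, demand) as *not applicable*
and report *unverifiable* — never a silent pass — when a formula or charge
is missing.

## Flux balance analysis

Steady state `S·v = 0` with per-reaction bounds; reversible reactions use
the conventional default magnitude M = 1000 flux units, and flux activity is
tested at ε = 10⁻⁶. The optimum is *minimum total uptake at fixed biomass
rate*: the biomass flux is fixed by an equality constraint (default rate 1.0
arbitrary units — the convention fixes a rate but its absolute value is
immaterial in a linear model, as the scaling test verifies), and the
objective counts only the negative part of each exchange flux through one
auxiliary variable per costed exchange (`u_j ≥ −v_j, u_j ≥ 0`). Freely
exchanged species (O₂, H₂O, CO₂ by default) carry no cost. LPs and MILPs are
solved with the HiGHS backends in SciPy. Because alternate optima are
common, tests assert objective values and feasibility, never specific flux
vectors. Currency metabolites are *not* removed in FBA — cofactor balancing
is part of the flux problem; they are pruned only from graph analyses.

`can_carry_flux` is the shared feasibility primitive (gap filling,
validation, essentiality): it asks for a steady-state vector with the probed
reaction's flux at least ε in the requested direction.

## Gap filling

Candidates are one irreversible transporter per (metabolite, topology edge,
direction); the species on the far side is instantiated on demand.
The MILP gates each candidate's flux by a binary indicator with big-M = 1000
and minimises the indicator sum subject to `S·v = 0` and a biomass-flux
requirement (default threshold 1.0, well above ε to keep the MILP
numerically comfortable), so the returned cardinality is certified minimal
— matching the method's claim of a *minimal* transporter set — rather than
greedy. Ties among equal-cardinality optima are broken deterministically by
a secondary cost (< 1 in total, so cardinality is never affected) that
prefers candidates passing both audit criteria, then lexicographic id.
`max_cardinality` defaults to 20 to bound the search.

The audit mirrors manual curation. Criterion (i) fails when the addition
would reverse an existing irreversible transporter of the same metabolite
over the same edge. Criterion (ii) holds when some reaction produces the
metabolite in the origin compartment and some reaction consumes it in the
destination; a reversible exchange counts as production in the extracellular
space, since an uptake makes the nutrient available there. Failing flags
mark a transporter for review; they never remove it.

## Reaction graph

Nodes are reactions (one node per reaction — reversibility contributes
edge orientations, not duplicate nodes, keeping node count equal to reaction
count). A directed edge runs producer → consumer of the same species in the
same compartment; currency metabolites are excluded from edge formation in
every compartment; self-loops are excluded. Parallel shared-metabolite edges
collapse to one labelled edge, so density `|E|/(N(N−1))`, diameter and
average path length are computed on a simple digraph. Average path length is
taken over *connected ordered pairs only* (unreachable pairs are excluded,
the convention of common graph-visualisation tools); this choice is stated
here prominently because conventions differ and it changes the number.
Compartment-unique metabolite analysis reports base identities whose entire
compartment footprint is a single compartment, again excluding currency
species.

## Functional validation and essentiality

A validation case closes the uptake direction of every exchange except the
case's sources and the free species, leaves every non-exchange bound
untouched (the most literal reading of "without violating the other model
constraints"), injects sources that lack an exchange reaction directly in
their own compartment, adds a demand sink for the target in the target's
compartment, and tests demand feasibility at ε. Suites evaluate cases
independently; a bad case records an error and never aborts the batch.

Essential reactions are found by single deletion (bounds → 0). The fast scan
deletes only reactions active in one feasible witness; this is exact, not
heuristic, because a reaction idle in a feasible witness can be deleted
while keeping that witness. The exhaustive flag exists to audit that
argument, and the test suite does so on every generator fixture.

## Synthetic model generator

The generator emulates, at toy scale, the structures the analyses consume:
an extracellular space with reversible nutrient exchanges (influx negative),
linear backbone pathways that cross compartments through dedicated
transporters along the default topology and end in biomass precursors, a
biomass reaction consuming at least three precursors in at least two
compartments, a mass-balanced ATP/ADP/Pᵢ cofactor loop to exercise currency
removal, an unproducible dead-end branch as a reachability negative, and
random intra-compartment side branches. Defaults (4 compartments, 3
nutrient uptakes, 3-step chains, 30 % reversible steps, 4 side branches)
give models of roughly 25–30 reactions — large enough to exercise every
code path, small enough that exhaustive oracles (vertex enumeration, subset
search, full deletion scans) remain affordable in the test suite.

Two construction rules give exact ground truth. Side branches stay inside a
compartment and only *leave* the backbone, so each backbone transporter is
the unique inter-compartment route for its metabolite: planted gaps (removal
of individually biomass-critical transporters) are therefore uniquely
recoverable and recorded essentiality sets are exact. All randomness flows
through one seeded PRNG, and the seed is recorded in the SBML notes; the
same spec and seed reproduce the model byte-for-byte through the writer.

What the generator does **not** emulate: realistic biochemistry (its
formulae are placeholders chosen only to satisfy mass balance), dense
cross-pathway coupling, alternate transport routes, or GPR complexity
(one gene per backbone step). Passing tests therefore demonstrate
correctness of the algorithms under known ground truth, not performance on
a curated genome-scale reconstruction; the full-model statistics
(composition counts, density/diameter/path length) are computable on any
local SBML file through the same public functions.

## Serialisation

Written SBML is Level 3 Version 1 with the `fbc` package: bounds as shared
global parameters, formula/charge as fbc species attributes, gene products
and id-matched gene-product associations. Surface orientation, base-reaction
identity, reaction type, topology, currency list and biomass id travel in a
dedicated annotation namespace (`urn:compartgem:annotations`) because core
SBML has no such concepts. The reader also accepts Level 2 files with
COBRA-style notes (`GENE_ASSOCIATION`) and kinetic-law bound parameters;
missing metadata degrades to defaults (reaction type inferred from
stoichiometry, base id by suffix-stripping, lumen interface) rather than
failing. Element ordering on write is sorted, so equal models produce
byte-identical files. CSV table dialects (transporters, pathways,
uptake/biomass, validations, simulation exchanges) are UTF-8 with
`;`-separated list cells; unknown columns round-trip untouched.

## Numerical choices and limitations

* LP/MILP tolerance: steady-state residual ≤ 10⁻⁶ is asserted on optima;
  objective comparisons in tests use the same 10⁻⁶.
* The MILP certifies minimality only over the supplied candidate set;
  enlarging the set can only keep or reduce the minimum (tested).
* Vertex-enumeration and subset-search oracles are exponential and are used
  only at fixture scale (≤ 7 reactions, ≤ 12 candidates).
* Unbounded minimise-uptake problems cannot arise with finite default
  bounds; the status is still mapped for models built with infinite bounds.
* Gap filling proposes irreversible transporters only; a reversible carrier
  is represented by selecting both directions independently, which keeps
  audit criterion (i) easy to honour.
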
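"""Reaction-centred network construction and statistics.

Nodes are reactions; a directed edge runs from a reaction that produces a
metabolite to a reaction that consumes the same metabolite (same chemical
species in the same compartment).  For reversible reactions both orientations
contribute producer and consumer roles independently, but the reaction stays
a single node.  Currency metabolites — ubiquitous cofactors such as ATP and
water — are removed before edge formation in every compartment where they
occur, since their promiscuity would otherwise connect nearly everything to
nearly everything.

Statistics are computed on the simple digraph (parallel shared-metabolite
edges collapsed; the shared metabolites survive as an edge label):

density
    ``|E| / (N (N - 1))``.
diameter
    the largest finite shortest-path distance over ordered node pairs.
average path length
    the mean shortest-path distance over ordered pairs that are connected;
    unreachable pairs are excluded rather than treated as infinite.
"""

from __future__ import annotations

from typing import Iterable

import networkx as nx

from .model import Model


def build_graph(model: Model, currency_list: Iterable[str] | None = None) -> nx.DiGraph:
    """Directed reaction graph with currency metabolites removed.

    Parameters
    ----------
    model
        Source model; every reaction becomes a node.
    currency_list
        Base ids to exclude from edge formation; defaults to the model's own
        currency list.
    """
    currency = frozenset(
        model.currency_list if currency_list is None else currency_list
    )
    graph = nx.DiGraph()
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        graph.add_node(
            rid,
            rtype=rxn.rtype,
            compartments=",".join(sorted(model.reaction_compartments(rxn))),
        )
    producers: dict[str, set[str]] = {}
    consumers: dict[str, set[str]] = {}
    for rid in sorted(model.reactions):
        rxn = model.reactions[rid]
        for mid, coeff in rxn.stoichiometry.items():
            if model.metabolites[mid].base_id in currency:
                continue
            if coeff > 0 or rxn.reversible:
                producers.setdefault(mid, set()).add(rid)
            if coeff < 0 or rxn.reversible:
                consumers.setdefault(mid, set()).add(rid)
    edge_labels: dict[tuple[str, str], set[str]] = {}
    for mid, prods in producers.items():
        for src in prods:
            for dst in consumers.get(mid, ()):
                if src == dst:
                    continue  # no self-loop through a reaction's own species
                edge_labels.setdefault((src, dst), set()).add(mid)
    for (src, dst), mids in sorted(edge_labels.items()):
        graph.add_edge(src, dst, metabolites=";".join(sorted(mids)))
    return graph


def density(graph: nx.DiGraph) -> float:
    """Edge density of the simple digraph; requires at least two nodes."""
    n = graph.number_of_nodes()
    if n < 2:
        raise ValueError("density is undefined for graphs with fewer than 2 nodes")
    return graph.number_of_edges() / (n * (n - 1))


def _finite_distances(graph: nx.DiGraph) -> list[int]:
    out: list[int] = []
    for _, dists in nx.all_pairs_shortest_path_length(graph):
        out.extend(d for d in dists.values() if d > 0)
    return out


def diameter(graph: nx.DiGraph) -> int:
    """Largest finite shortest-path distance over ordered pairs."""
    if graph.number_of_nodes() < 2:
        raise ValueError("diameter is undefined for graphs with fewer than 2 nodes")
    dists = _finite_distances(graph)
    if not dists:
        raise ValueError("graph has no finite directed path between distinct nodes")
    return max(dists)


def average_path_length(graph: nx.DiGraph) -> float:
    """Mean shortest-path distance over connected ordered pairs."""
    if graph.number_of_nodes() < 2:
        raise ValueError(
            "average path length is undefined for graphs with fewer than 2 nodes"
        )
    dists = _finite_distances(graph)
    if not dists:
        raise ValueError("graph has no finite directed path between distinct nodes")
    return sum(dists) / len(dists)


def graph_stats(graph: nx.DiGraph) -> dict[str, float]:
    return {
        "nodes": graph.number_of_nodes(),
        "edges": graph.number_of_edges(),
        "density": density(graph),
        "diameter": diameter(graph),
        "average_path_length": average_path_length(graph),
    }


def compartment_unique_metabolites(model: Model) -> dict[str, set[str]]:
    """Metabolite identities confined to a single compartment.

    Currency metabolites are excluded, consistent with their removal from all
    network analyses.  Returns ``compartment -> set of base ids`` containing
    only identities whose full compartment footprint has size one.
    """
    footprint: dict[str, set[str]] = {}
    for met in model.metabolites.values():
        if met.base_id in model.currency_list:
            continue
        footprint.setdefault(met.base_id, set()).add(met.compartment)
    out: dict[str, set[str]] = {}
    for base, comps in footprint.items():
        if len(comps) == 1:
            (comp,) = comps
            out.setdefault(comp, set()).add(base)
    return out


def export_graph(graph: nx.DiGraph, path: str, fmt: str = "graphml") -> None:
    """Write the graph as GraphML or GML with deterministic ordering."""
    ordered = nx.DiGraph()
    ordered.add_nodes_from(sorted(graph.nodes(data=True)))
    ordered.add_edges_from(sorted(graph.edges(data=True)))
    if fmt == "graphml":
        nx.write_graphml(ordered, path)
    elif fmt == "gml":
        nx.write_gml(ordered, path)
    else:
        raise ValueError(f"unknown graph format {fmt!r} (use graphml or gml)")
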
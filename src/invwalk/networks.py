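"""Graph views of mutation combinatorics and fitness landscapes.

Four graph objects describe how an operator wires the genotype space:

* the *mutation multigraph* m(x): one directed edge per operator
  application at x, so degenerate inversions appear as parallel edges
  and invariant inversions as self-loops;
* its *reduced graph* M(x): the underlying simple graph (loops
  dropped, parallel edges collapsed), a star whose leaf count is the
  accessible-mutant number D_v(x);
* the *mutational network* M(X) = union of M(x) over all 2**N
  genotypes — the Hamming graph H(N, 2) for point mutations, a denser
  rewiring for inversions (node degree = D_v(x), mean degree <kappa>);
* the *fitness network* F: the mutational network made directed, with
  an edge x -> x' only when f(x') > f(x).  It is acyclic, and its
  sinks (out-degree 0) are exactly the operator's local fitness peaks.

All functions return networkx graphs whose nodes are genome bit
strings such as ``"0101"``; GraphML export keeps operator loci and
Hamming-distance edge attributes.
"""

from __future__ import annotations

from typing import Hashable

import networkx as nx
import numpy as np

from .genomes import (
    DEFAULT_ENUMERATION_CAP,
    Genome,
    OperatorKind,
    Topology,
    all_genomes,
    apply_op,
    enumerate_mutants,
    enumerate_operations,
    hamming_distance,
)
from .landscapes import NKLandscape


def genome_label(g: Genome) -> str:
    return str(g)


def build_multigraph(
    g: Genome, kind: OperatorKind, max_segment: int | None = None
) -> nx.MultiDiGraph:
    """The directed mutation multigraph m(x) of one origin genome.

    Vertices are the origin and its accessible mutants; every operator
    application contributes one edge labelled with its loci (i, j) and
    the Hamming distance it spans.  Self-loops mark invariant
    inversions.
    """
    m = nx.MultiDiGraph(origin=str(g), kind=kind, topology=g.topology)
    origin = genome_label(g)
    m.add_node(origin)
    for op in enumerate_operations(len(g), kind, g.topology, max_segment):
        target = apply_op(g, op)
        m.add_edge(
            origin,
            genome_label(target),
            i=op.i,
            j=op.j,
            hamming=hamming_distance(g, target),
        )
    return m


def reduce_multigraph(m: nx.MultiDiGraph) -> nx.Graph:
    """The underlying simple graph M(x): no loops, no parallel edges."""
    M = nx.Graph(**m.graph)
    M.add_nodes_from(m.nodes)
    M.add_edges_from((u, v) for u, v in m.edges() if u != v)
    return M


def build_mutational_network(
    N: int,
    kind: OperatorKind,
    topology: Topology = "circular",
    max_segment: int | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> nx.Graph:
    """The mutational network M(X) over the full genotype space.

    Undirected and simple; the degree of x equals D_v(x).  For point
    mutations this is the Hamming graph H(N, 2) (the hypercube).
    """
    G = nx.Graph(N=N, kind=kind, topology=topology)
    for g in all_genomes(N, topology, cap):
        label = genome_label(g)
        G.add_node(label)
        for mut in enumerate_mutants(g, kind, max_segment):
            G.add_edge(label, genome_label(mut))
    return G


def mean_degree(G: nx.Graph) -> float:
    """The mean node degree <kappa> (mean mutability) of a network."""
    degs = [d for _, d in G.degree()]
    return float(np.mean(degs))


def build_fitness_network(
    landscape: NKLandscape,
    kind: OperatorKind,
    topology: Topology = "circular",
    max_segment: int | None = None,
    cap: int = DEFAULT_ENUMERATION_CAP,
) -> nx.DiGraph:
    """The fitness network F: edges point strictly uphill in fitness.

    Nodes carry their fitness value; an edge x -> x' exists iff x' is
    an accessible mutant of x and f(x') > f(x).  Equal-fitness pairs
    produce no edge, so the network is acyclic and its sinks are the
    operator's local optima.
    """
    N = landscape.N
    F = nx.DiGraph(
        N=N, kind=kind, topology=topology, landscape=landscape.to_json()
    )
    fitness: dict[str, float] = {}
    genomes = list(all_genomes(N, topology, cap))
    for g in genomes:
        label = genome_label(g)
        fitness[label] = landscape.fitness(g)
        F.add_node(label, fitness=fitness[label])
    for g in genomes:
        label = genome_label(g)
        for mut in enumerate_mutants(g, kind, max_segment):
            mlabel = genome_label(mut)
            if fitness[mlabel] > fitness[label]:
                F.add_edge(label, mlabel)
    return F


def local_optima(F: nx.DiGraph) -> set[str]:
    """Sinks of the fitness network: genotypes with no fitter mutant."""
    return {v for v in F.nodes if F.out_degree(v) == 0}


def layered_layout(F: nx.DiGraph) -> dict[Hashable, int]:
    """Longest-path layering of an acyclic fitness network.

    Each node is assigned to the first possible layer such that all its
    predecessors lie in strictly earlier layers.  Raises on cycles
    (which would indicate a fitness-tie bug upstream).
    """
    try:
        generations = nx.topological_generations(F)
        return {v: layer for layer, nodes in enumerate(generations) for v in nodes}
    except nx.NetworkXUnfeasible as exc:
        raise ValueError("fitness network contains a cycle") from exc


def degree_table(G: nx.Graph) -> "list[tuple[str, int]]":
    """(genotype, degree) rows, sorted by genotype label."""
    return sorted((str(v), int(d)) for v, d in G.degree())


def write_graphml(G: "nx.Graph | nx.DiGraph | nx.MultiDiGraph", path) -> None:
    """GraphML export; edge labels (i, j) and Hamming attributes survive."""
    nx.write_graphml(G, str(path))
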
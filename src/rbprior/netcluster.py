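"""Disease-gene network construction and MCODE complex detection.

MCODE is implemented from scratch on the unweighted topology:

1. Vertex weighting. For each vertex v, take the subgraph induced by its
   closed neighborhood N[v], find the highest k-core of that subgraph (the
   maximal subgraph of minimum degree k for the largest feasible k), and set
   weight(v) = k * density(core), with density = 2|E| / (|V| (|V|-1)).
   Isolated vertices weigh 0.

2. Complex prediction. Unvisited vertices seed complexes in descending
   weight order (ties broken lexicographically). From a seed, a
   breadth-first expansion admits unvisited neighbors whose weight is at
   least seed_weight * (1 - node_score_cutoff); every admitted vertex is
   marked visited, so complexes are vertex-disjoint. Optional post-passes:
   haircut removes members with a single connection inside the complex;
   fluff adds outside neighbors whose closed-neighborhood density exceeds
   the fluff threshold. A complex scores density * size.

Edge weights from the functional network are carried along for reporting
but never influence the clustering — the algorithm is topological.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import networkx as nx

__all__ = [
    "Complex",
    "CatalogMatch",
    "build_disease_network",
    "mcode_vertex_weight",
    "mcode_find_complexes",
    "annotate_complex",
]


class ClusterError(ValueError):
    pass


@dataclass(frozen=True)
class Complex:
    members: frozenset[str]
    score: float  # density * |members|
    seed_node: str

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class CatalogMatch:
    catalog_name: str
    n_matched: int
    coverage: float  # n_matched / |complex|


def build_disease_network(
    funcnet: nx.Graph,
    seeds: Iterable[str],
    rbp_set: set[str],
    cdg_set: set[str],
) -> tuple[nx.Graph, list[str]]:
    """One-hop disease network around the seed genes, filtered by class.

    Keeps (seeds ∪ neighbors-of-seeds) ∩ (rbp_set ∪ cdg_set ∪ seeds) as an
    induced subgraph of the functional network. Node attribute ``klass``
    records seed / both / rbp / cdg. Seeds absent from the network are
    reported (second return value); an entirely empty result is returned as
    an empty graph rather than an error.
    """
    seeds = sorted(set(seeds))
    missing = [s for s in seeds if s not in funcnet]
    present = [s for s in seeds if s in funcnet]
    hop = set(present)
    for s in present:
        hop.update(funcnet.neighbors(s))
    allowed = (rbp_set | cdg_set | set(seeds)) & hop
    graph = funcnet.subgraph(allowed).copy()
    for node in graph.nodes:
        if node in seeds:
            klass = "seed"
        elif node in rbp_set and node in cdg_set:
            klass = "both"
        elif node in rbp_set:
            klass = "rbp"
        else:
            klass = "cdg"
        graph.nodes[node]["klass"] = klass
    return graph, missing


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _highest_k_core(graph: nx.Graph) -> tuple[int, nx.Graph]:
    """(k, core subgraph) for the largest k with a non-empty k-core."""
    if graph.number_of_edges() == 0:
        return 0, graph.subgraph([])
    core_numbers = nx.core_number(graph)
    k = max(core_numbers.values())
    core = graph.subgraph([v for v, c in core_numbers.items() if c >= k])
    return k, core


def mcode_vertex_weight(graph: nx.Graph, v: str) -> float:
    """k-core-weighted local density of v's closed neighborhood."""
    if v not in graph:
        raise ClusterError(f"vertex {v!r} not in graph")
    closed = [v, *graph.neighbors(v)]
    sub = graph.subgraph(closed)
    k, core = _highest_k_core(sub)
    if k == 0:
        return 0.0
    return k * _density(core)


def mcode_find_complexes(
    graph: nx.Graph,
    node_score_cutoff: float = 0.1,
    fluff: float = 0.0,
    haircut: bool = False,
) -> list[Complex]:
    """Seed-and-expand complex prediction over the whole graph.

    Returns complexes of size >= 2 in descending score order (ties broken
    by seed id). Parameters mirror the reference tool: node_score_cutoff in
    [0, 1) bounds how far member weights may fall below the seed's; fluff
    and haircut are the optional post-processing passes described above.
    """
    if not 0.0 <= node_score_cutoff < 1.0:
        raise ClusterError("node_score_cutoff must be in [0, 1)")
    if fluff < 0:
        raise ClusterError("fluff threshold must be >= 0")
    weights = {v: mcode_vertex_weight(graph, v) for v in graph.nodes}
    order = sorted(weights, key=lambda v: (-weights[v], str(v)))
    visited: set[str] = set()
    complexes: list[Complex] = []

    for seed in order:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - node_score_cutoff)
        members = {seed}
        visited.add(seed)
        frontier = [seed]
        while frontier:
            nxt: list[str] = []
            for u in frontier:
                for w in sorted(graph.neighbors(u), key=str):
                    if w in visited:
                        continue
                    if weights[w] >= threshold:
                        visited.add(w)
                        members.add(w)
                        nxt.append(w)
            frontier = nxt

        if haircut:
            sub = graph.subgraph(members)
            members = {v for v in members if sub.degree(v) > 1} or members & {seed}
        if fluff > 0:
            halo: set[str] = set()
            for u in sorted(members, key=str):
                for w in sorted(graph.neighbors(u), key=str):
                    if w in visited or w in halo:
                        continue
                    closed = [w, *graph.neighbors(w)]
                    if _density(graph.subgraph(closed)) > fluff:
                        halo.add(w)
            members |= halo
            visited |= halo
        if len(members) >= 2:
            complexes.append(
                Complex(
                    members=frozenset(members),
                    score=_density(graph.subgraph(members)) * len(members),
                    seed_node=seed,
                )
            )
    complexes.sort(key=lambda c: (-c.score, str(c.seed_node)))
    return complexes


def annotate_complex(complex_members: Iterable[str], catalog: dict[str, set[str]]) -> CatalogMatch | None:
    """Best catalog entry by member overlap.

    Maximizes the number of matched members; ties break by higher coverage
    (matched / complex size) and then lexicographic catalog name. Returns
    None for an empty catalog.
    """
    members = set(complex_members)
    if not catalog or not members:
        return None
    best: CatalogMatch | None = None
    for name in sorted(catalog):
        n_matched = len(members & catalog[name])
        coverage = n_matched / len(members)
        candidate = CatalogMatch(catalog_name=name, n_matched=n_matched, coverage=coverage)
        if best is None or (candidate.n_matched, candidate.coverage) > (best.n_matched, best.coverage):
            best = candidate
    return best
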
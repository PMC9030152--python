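"""Confidence-filtered protein-protein interactions and the RBP-BC bipartite net.

Edges carry a per-channel confidence score in [0, 1] (STRING-style). The
default filter keeps experimental and curated-database evidence at the
highest-confidence preset (score >= 0.9, inclusive); an interaction passes
if any allowed channel meets the score. The bipartite extraction keeps only
edges joining a breast-cancer protein to an RNA-binding protein; genes that
belong to both sets appear on both sides and are reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

__all__ = [
    "CHANNELS",
    "DEFAULT_CHANNELS",
    "BipartiteNetwork",
    "filter_edges",
    "extract_bipartite",
    "interactor_counts",
]

CHANNELS = ("experimental", "database", "textmining", "coexpression", "other")
DEFAULT_CHANNELS = frozenset({"experimental", "database"})


class PPIError(ValueError):
    pass


@dataclass
class BipartiteNetwork:
    """Cross-set interaction network: left = BC proteins, right = RBPs."""

    graph: nx.Graph
    left: frozenset[str]
    right: frozenset[str]
    dual_membership: frozenset[str] = field(default_factory=frozenset)

    def degree(self, gene: str) -> int:
        return self.graph.degree(gene) if gene in self.graph else 0

    def right_with_edges(self) -> set[str]:
        return {g for g in self.right if self.degree(g) > 0}

    def left_with_edges(self) -> set[str]:
        return {g for g in self.left if self.degree(g) > 0}


def filter_edges(
    edges: pd.DataFrame,
    allowed_channels: frozenset[str] = DEFAULT_CHANNELS,
    min_score: float = 0.9,
) -> pd.DataFrame:
    """Keep edges whose channel is allowed and whose score is >= min_score."""
    required = {"gene_a", "gene_b", "channel", "score"}
    if not required.issubset(edges.columns):
        raise PPIError(f"edge table lacks columns {sorted(required - set(edges.columns))}")
    scores = edges["score"].astype(float)
    if ((scores < 0) | (scores > 1)).any():
        bad = edges.loc[(scores < 0) | (scores > 1)].iloc[0]
        raise PPIError(f"score {bad['score']} outside [0,1] on edge {bad['gene_a']}-{bad['gene_b']}")
    keep = edges["channel"].isin(allowed_channels) & (scores >= min_score)
    return edges.loc[keep].reset_index(drop=True)


def extract_bipartite(edges: pd.DataFrame, bc_set: set[str], rbp_set: set[str]) -> BipartiteNetwork:
    """Bipartite network of filtered edges between BC proteins and RBPs.

    Only cross-set edges are retained (an edge must join one BC protein and
    one RBP, in either column order). Per-channel rows for one pair collapse
    to a single undirected edge holding the best score.
    """
    dual = frozenset(bc_set & rbp_set)
    graph = nx.Graph()
    for row in edges.itertuples(index=False):
        a, b, score = row.gene_a, row.gene_b, float(row.score)
        if a == b:
            continue
        cross = (a in bc_set and b in rbp_set) or (b in bc_set and a in rbp_set)
        if not cross:
            continue
        if graph.has_edge(a, b):
            graph[a][b]["score"] = max(graph[a][b]["score"], score)
        else:
            graph.add_edge(a, b, score=score)
    return BipartiteNetwork(
        graph=graph,
        left=frozenset(bc_set),
        right=frozenset(rbp_set),
        dual_membership=dual,
    )


def interactor_counts(net: BipartiteNetwork) -> tuple[int, int, list[tuple[str, int]]]:
    """(#BC proteins with >=1 edge, #RBPs with >=1 edge, hub list).

    Hubs are BC-side proteins ranked by descending degree, ties broken
    lexicographically by gene id.
    """
    left = net.left_with_edges()
    right = net.right_with_edges()
    hubs = sorted(((g, net.degree(g)) for g in left), key=lambda t: (-t[1], t[0]))
    return len(left), len(right), hubs
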
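"""Offline functional context: gene-set over-representation and network hubs.

Over-representation uses the upper-tail hypergeometric test of a query
protein set against user-supplied gene-set collections (GMT files), with
Benjamini-Hochberg adjustment across sets. "Core" proteins are the nodes
in the top 10% of degree centrality of a user-supplied interaction edge
list, with boundary ties included. No live database access: collections
and networks are versioned input files.
"""
from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .prote_de import bh_adjust

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSetCollection",
    "EnrichmentResult",
    "InteractionNetwork",
    "read_gmt",
    "read_edge_list",
    "hypergeom_enrich",
    "degree_core",
]

CORE_TOP_FRACTION = 0.10


@dataclass
class GeneSetCollection:
    sets: dict[str, frozenset]
    universe: frozenset

    @classmethod
    def from_sets(cls, sets: dict, universe) -> "GeneSetCollection":
        """Filter member ids to the universe; dropped ids are logged."""
        uni = frozenset(str(u) for u in universe)
        filtered = {}
        for name, members in sets.items():
            m = frozenset(str(x) for x in members)
            dropped = m - uni
            if dropped:
                logger.info("set %s: dropped %d ids outside the universe",
                            name, len(dropped))
            filtered[name] = m & uni
        return cls(sets=filtered, universe=uni)


@dataclass(frozen=True)
class EnrichmentResult:
    set_name: str
    overlap: int
    set_size: int
    query_size: int
    universe_size: int
    p_value: float
    p_adjusted: float
    overlap_ids: frozenset


@dataclass
class InteractionNetwork:
    graph: nx.Graph = field(repr=False, default_factory=nx.Graph)

    @classmethod
    def from_edges(cls, edges) -> "InteractionNetwork":
        """Undirected graph from id pairs; duplicates and self-loops removed."""
        g = nx.Graph()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                continue
            g.add_edge(u, v)
        return cls(graph=g)

    @property
    def degree(self) -> dict[str, int]:
        return dict(self.graph.degree())


def read_gmt(path) -> dict[str, frozenset]:
    """Read a GMT file: tab-separated set name, description, member ids."""
    sets = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:80]!r}")
            sets[parts[0]] = frozenset(p for p in parts[2:] if p)
    return sets


def read_edge_list(path) -> list[tuple[str, str]]:
    """Two-column TSV edge list (node_a, node_b); a header line is allowed."""
    edges = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2 or not parts[0]:
                continue
            if i == 0 and parts[0].lower() in ("node_a", "source", "protein1"):
                continue
            edges.append((parts[0], parts[1]))
    return edges


def hypergeom_enrich(query, collection: GeneSetCollection) -> list[EnrichmentResult]:
    """Upper-tail hypergeometric over-representation of a query in each set.

    p = P(X >= overlap), X ~ Hypergeom(universe, set_size, query_size); BH
    adjusted across all sets in the collection. Query ids outside the
    universe are dropped with a warning.
    """
    q = frozenset(str(x) for x in query)
    if not collection.universe:
        raise ValueError("empty universe")
    outside = q - collection.universe
    if outside:
        warnings.warn(f"dropping {len(outside)} query ids outside the universe")
        q = q & collection.universe
    if not q:
        raise ValueError("empty query after universe filtering")
    M = len(collection.universe)
    N = len(q)
    rows = []
    for name, members in collection.sets.items():
        K = len(members)
        ov = q & members
        p = float(hypergeom.sf(len(ov) - 1, M, K, N))
        rows.append((name, ov, K, p))
    padj = bh_adjust([r[3] for r in rows]) if rows else []
    return [EnrichmentResult(set_name=name, overlap=len(ov), set_size=K,
                             query_size=N, universe_size=M, p_value=p,
                             p_adjusted=float(pa), overlap_ids=frozenset(ov))
            for (name, ov, K, p), pa in zip(rows, padj)]


def degree_core(network: InteractionNetwork,
                top_fraction: float = CORE_TOP_FRACTION) -> set[str]:
    """Nodes in the top fraction of degree centrality, boundary ties included.

    k = ceil(top_fraction * node count); the core is the k highest-degree
    nodes plus every node tied with the k-th degree.
    """
    deg = network.degree
    if not deg:
        raise ValueError("network has no nodes")
    nodes = sorted(deg, key=lambda n: (-deg[n], n))
    k = math.ceil(top_fraction * len(nodes))
    cutoff = deg[nodes[k - 1]]
    if cutoff == 0:
        warnings.warn("degree-0 cutoff: every node qualifies as core")
    return {n for n in nodes if deg[n] >= cutoff}


def enrichment_table(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "set_name": r.set_name, "overlap": r.overlap, "set_size": r.set_size,
        "query_size": r.query_size, "universe_size": r.universe_size,
        "p_value": r.p_value, "p_adjusted": r.p_adjusted,
        "overlap_ids": ";".join(sorted(r.overlap_ids)),
    } for r in results])
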
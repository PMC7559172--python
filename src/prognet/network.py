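"""Scored-interaction network analysis: edge filtering, centralities,
triple-centrality hub screening, and MCODE module detection.

The intended input is a STRING-style protein–protein association network in
which each edge carries a combined confidence score in [0, 1]; edges above a
confidence threshold (0.4 by convention) form the analysis graph.

Hub screening intersects the top-ranked nodes of three centralities (degree,
betweenness, closeness); MCODE finds locally dense modules by k-core-based
vertex weighting followed by greedy seeded expansion, and scores each module
as density × size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "NetworkModule",
    "filter_edges",
    "centralities",
    "select_hubs",
    "mcode",
    "module_score",
    "average_neighbors",
]


@dataclass
class NetworkModule:
    """A detected dense module: its nodes, edge count, density and score."""

    nodes: tuple[str, ...]
    n_edges: int
    seed: str

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def density(self) -> float:
        n = self.n_nodes
        if n < 2:
            return 0.0
        return 2.0 * self.n_edges / (n * (n - 1))

    @property
    def score(self) -> float:
        """MCODE module score: density × node count = 2E/(N-1)."""
        return module_score(self.n_nodes, self.n_edges)


def module_score(n_nodes: int, n_edges: int) -> float:
    """MCODE cluster score for a module of ``n_nodes`` and ``n_edges``:
    ``density * n_nodes = 2 * n_edges / (n_nodes - 1)``."""
    if n_nodes < 2:
        raise ValueError("a module needs at least 2 nodes")
    if n_edges < 0 or n_edges > n_nodes * (n_nodes - 1) // 2:
        raise ValueError(
            f"impossible edge count {n_edges} for {n_nodes} nodes"
        )
    return 2.0 * n_edges / (n_nodes - 1)


def filter_edges(graph: nx.Graph, min_score: float = 0.4, strict: bool = True) -> nx.Graph:
    """Keep edges with confidence score above ``min_score``.

    The comparison is strict (``score > min_score``) by default, matching a
    "combined score of > 0.4" criterion; set ``strict=False`` for the
    ``>=`` convention.  Nodes left isolated are dropped.  The input graph is
    not modified.  Every edge must carry a ``score`` attribute.
    """
    out = nx.Graph()
    for a, b, data in graph.edges(data=True):
        if "score" not in data:
            raise ValueError(f"edge {a}–{b} has no score attribute")
        keep = data["score"] > min_score if strict else data["score"] >= min_score
        if keep:
            out.add_edge(a, b, **data)
    return out


def centralities(graph: nx.Graph) -> pd.DataFrame:
    """Degree, betweenness and closeness centrality per node.

    Degree is the incident-edge count; betweenness is the unnormalized
    shortest-path pair count (Brandes accumulation, unweighted); closeness is
    Freeman closeness within each connected component,
    ``(n_c - 1) / sum of distances``, with isolated nodes assigned 0.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("centralities undefined on an empty graph")
    deg = dict(graph.degree())
    btw = nx.betweenness_centrality(graph, normalized=False)
    # wf_improved=False gives per-component Freeman closeness; isolated -> 0
    clo = nx.closeness_centrality(graph, wf_improved=False)
    df = pd.DataFrame({"node": sorted(graph.nodes(), key=str)})
    df["degree"] = [deg[n] for n in df["node"]]
    df["betweenness"] = [btw[n] for n in df["node"]]
    df["closeness"] = [clo[n] for n in df["node"]]
    return df


def select_hubs(graph: nx.Graph, k: int = 10) -> list[str]:
    """Top-``k`` hubs shared by all three centrality rankings.

    The cutoff ``m`` expands from ``k`` until the intersection of the top-m
    nodes by degree, by betweenness and by closeness has at least ``k``
    members; the intersection is ordered by degree (desc), then betweenness
    (desc), then node name, and the first ``k`` returned.  If the
    intersection never reaches ``k`` (only possible through ties exhausting
    the node list), the final intersection is returned with a warning.
    """
    if k < 1:
        raise ValueError("k must be positive")
    if graph.number_of_nodes() < k:
        raise ValueError(f"graph has fewer than k={k} nodes")
    table = centralities(graph)
    # rank each measure descending, node name as deterministic tie-break
    orders = {
        m: list(table.sort_values([m, "node"], ascending=[False, True])["node"])
        for m in ("degree", "betweenness", "closeness")
    }
    n = len(table)
    for m in range(k, n + 1):
        shared = set(orders["degree"][:m])
        shared &= set(orders["betweenness"][:m])
        shared &= set(orders["closeness"][:m])
        if len(shared) >= k:
            break
    else:
        logger.warning(
            "hub intersection reached only %d of %d requested nodes", len(shared), k
        )
    lookup = table.set_index("node")
    ranked = sorted(
        shared,
        key=lambda v: (-lookup.at[v, "degree"], -lookup.at[v, "betweenness"], v),
    )
    return ranked[:k]


def average_neighbors(graph: nx.Graph) -> float:
    """Mean degree, ``2|E| / |V|`` (the "average number of neighbors")."""
    if graph.number_of_nodes() == 0:
        raise ValueError("average_neighbors undefined on an empty graph")
    return 2.0 * graph.number_of_edges() / graph.number_of_nodes()


def _density(graph: nx.Graph) -> float:
    n = graph.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * graph.number_of_edges() / (n * (n - 1))


def _highest_k_core(graph: nx.Graph) -> tuple[nx.Graph, int]:
    """The k-core with the largest k in ``graph`` (the innermost core)."""
    if graph.number_of_edges() == 0:
        return graph.subgraph([]).copy(), 0
    core_nums = nx.core_number(graph)
    k_max = max(core_nums.values())
    nodes = [v for v, c in core_nums.items() if c >= k_max]
    return graph.subgraph(nodes), k_max


def _vertex_weights(graph: nx.Graph) -> dict[str, float]:
    """MCODE vertex weighting: core-clustering coefficient of the closed
    neighborhood times its highest core number."""
    weights = {}
    for v in graph.nodes():
        closed = [v, *graph.neighbors(v)]
        sub = graph.subgraph(closed)
        core, k_max = _highest_k_core(sub)
        weights[v] = _density(core) * k_max
    return weights


def mcode(
    graph: nx.Graph,
    degree_cutoff: int = 2,
    node_score_cutoff: float = 0.2,
    k_core: int = 2,
    max_depth: int = 100,
    haircut: bool = True,
    fluff: bool = False,
    fluff_density: float = 0.1,
) -> list[NetworkModule]:
    """MCODE molecular-complex detection.

    Three stages: (1) vertex weighting — each node scores the density of the
    highest k-core of its closed neighborhood multiplied by that core's k
    (nodes below ``degree_cutoff`` score 0); (2) complex prediction — seeds
    are taken in descending weight order, and a complex grows breadth-first
    over unvisited neighbors whose weight is within ``node_score_cutoff`` of
    the seed weight (i.e. >= (1 - cutoff) * seed weight), to at most
    ``max_depth`` hops; (3) post-processing — complexes lacking a ``k_core``
    are discarded, ``haircut`` trims singly-connected nodes, and ``fluff``
    optionally adds boundary neighborhoods denser than ``fluff_density``.

    Modules are returned ordered by score (desc), size (desc), then seed.
    """
    weights = _vertex_weights(graph)
    for v in graph.nodes():
        if graph.degree(v) < degree_cutoff:
            weights[v] = 0.0
    # deterministic seed order: weight desc, then node name
    seeds = sorted(graph.nodes(), key=lambda v: (-weights[v], str(v)))
    visited: set = set()
    modules: list[NetworkModule] = []
    for seed in seeds:
        if seed in visited or weights[seed] <= 0:
            continue
        threshold = (1.0 - node_score_cutoff) * weights[seed]
        members = {seed}
        frontier = [seed]
        depth = 0
        while frontier and depth < max_depth:
            nxt = []
            for v in frontier:
                for nb in sorted(graph.neighbors(v), key=str):
                    if nb in visited or nb in members:
                        continue
                    if weights[nb] >= threshold:
                        members.add(nb)
                        nxt.append(nb)
            frontier = nxt
            depth += 1
        visited |= members
        sub = graph.subgraph(members).copy()
        core = nx.k_core(sub, k_core)
        if core.number_of_nodes() == 0:
            continue
        if haircut:
            # trim singly connected nodes (iteratively: the 2-core)
            sub = nx.k_core(sub, 2)
        if fluff:
            extra = set()
            for v in list(sub.nodes()):
                for nb in graph.neighbors(v):
                    if nb in sub or nb in extra:
                        continue
                    closed = [nb, *graph.neighbors(nb)]
                    if _density(graph.subgraph(closed)) > fluff_density:
                        extra.add(nb)
            sub = graph.subgraph(set(sub.nodes()) | extra).copy()
        if sub.number_of_nodes() < 2:
            continue
        modules.append(
            NetworkModule(
                nodes=tuple(sorted(sub.nodes(), key=str)),
                n_edges=sub.number_of_edges(),
                seed=seed,
            )
        )
    modules.sort(key=lambda m: (-m.score, -m.n_nodes, str(m.seed)))
    return modules
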
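"""Interaction-network construction, centrality, overlap, and hub contrast.

Direct-interaction subnetworks are induced on the genes a sample's qualifying
variants affect; an optional ``plus_bridges`` mode additionally admits
non-query nodes adjacent to at least two query genes (hub discovery: a
protein can be central to a mutated gene set without being mutated itself).

Centrality conventions (the measures are unweighted; conventions documented
because rank order, not raw value, is the comparison surface):

* degree — incident edge count,
* betweenness — Brandes' algorithm, unnormalized, endpoints excluded,
* closeness — Wasserman–Faust composite
  ``((r-1)/(n-1)) * ((r-1)/sum_u d(v,u))`` over the ``r`` nodes reachable
  from ``v``, which handles disconnected graphs (isolated node -> 0).
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .titv import Fisher2x2Result, fisher_exact_2x2

log = logging.getLogger(__name__)


class NetworkError(ValueError):
    pass


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two-column TSV of symbols -> simple undirected graph.

    Duplicate and reversed edges are deduplicated (count logged); self-loops
    are dropped.
    """
    graph = nx.Graph()
    n_dupes = n_loops = 0
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) < 2:
            raise NetworkError(f"{path}: line {i}: expected two tab-separated symbols")
        a, b = parts[0].strip(), parts[1].strip()
        if a == b:
            n_loops += 1
            continue
        if graph.has_edge(a, b):
            n_dupes += 1
            continue
        graph.add_edge(a, b)
    if n_dupes or n_loops:
        log.info("dropped %d duplicate and %d self-loop edges from %s",
                 n_dupes, n_loops, path)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("# gene_a\tgene_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges):
            fh.write(f"{a}\t{b}\n")


def edges_to_graph(edges: Iterable[tuple[str, str]]) -> nx.Graph:
    graph = nx.Graph()
    for a, b in edges:
        if a != b:
            graph.add_edge(a, b)
    return graph


def build_subnetwork(genes: Iterable[str], interactions, mode: str = "direct") -> nx.Graph:
    """Induce the query genes' subnetwork from a full interaction graph.

    ``direct``: induced subgraph on query genes present in the interaction
    graph.  ``plus_bridges``: additionally admits non-query nodes adjacent to
    >= 2 query genes, with their edges to query genes; bridge nodes carry the
    node attribute ``bridge=True``.
    """
    if mode not in ("direct", "plus_bridges"):
        raise NetworkError(f"unknown mode {mode!r}")
    full = interactions if isinstance(interactions, nx.Graph) else edges_to_graph(interactions)
    query = set(genes)
    if not query:
        raise NetworkError("empty query gene set")
    present = query & set(full.nodes)
    sub = nx.Graph(full.subgraph(present))
    nx.set_node_attributes(sub, False, "bridge")
    if mode == "plus_bridges":
        for node in sorted(set(full.nodes) - query):
            neighbors = set(full.neighbors(node)) & present
            if len(neighbors) >= 2:
                sub.add_node(node, bridge=True)
                for q in sorted(neighbors):
                    sub.add_edge(node, q)
    if sub.number_of_nodes() == 0:
        warnings.warn("query genes are disjoint from the interaction graph")
    return sub


def centrality(
    graph: nx.Graph,
    measures: Sequence[str] = ("degree", "betweenness", "closeness"),
) -> pd.DataFrame:
    """Per-node centrality report with per-measure ranks (1 = most central)."""
    known = {"degree", "betweenness", "closeness"}
    unknown = set(measures) - known
    if unknown:
        raise NetworkError(f"unknown centrality measures {sorted(unknown)}")
    nodes = sorted(graph.nodes)
    if not nodes:
        return pd.DataFrame(columns=list(measures))
    data = {}
    if "degree" in measures:
        data["degree"] = [graph.degree(v) for v in nodes]
    if "betweenness" in measures:
        bc = nx.betweenness_centrality(graph, normalized=False)
        data["betweenness"] = [bc[v] for v in nodes]
    if "closeness" in measures:
        cc = nx.closeness_centrality(graph, wf_improved=True)
        data["closeness"] = [cc[v] for v in nodes]
    report = pd.DataFrame(data, index=nodes)
    for m in measures:
        report[f"{m}_rank"] = (
            report[m].rank(ascending=False, method="min").astype(int)
        )
    return report


def largest_component_fraction(graph: nx.Graph, query_genes: Iterable[str]) -> float:
    """Percent of query genes inside the largest connected component.

    Query genes absent from the graph count as singleton components.  Ties
    between equally large components are broken toward the lexicographically
    smallest one (logged).
    """
    query = set(query_genes)
    if not query:
        raise NetworkError("empty query gene set")
    components = [set(c) for c in nx.connected_components(graph)]
    components += [{g} for g in sorted(query - set(graph.nodes))]
    components.sort(key=lambda c: (-len(c), min(c)))
    best = components[0]
    if len(components) > 1 and len(components[1]) == len(best):
        log.info("component-size tie broken toward %s", min(best))
    return 100.0 * len(best & query) / len(query)


def network_overlap(graph_a: nx.Graph, graph_b: nx.Graph) -> dict:
    """Shared nodes/edges, Jaccard indices, and shared-node centrality ranks."""
    nodes_a, nodes_b = set(graph_a.nodes), set(graph_b.nodes)
    edges_a = {tuple(sorted(e)) for e in graph_a.edges}
    edges_b = {tuple(sorted(e)) for e in graph_b.edges}
    shared_nodes = nodes_a & nodes_b
    shared_edges = edges_a & edges_b

    def jaccard(x, y):
        return len(x & y) / len(x | y) if (x | y) else 0.0

    out = {
        "shared_nodes": len(shared_nodes),
        "shared_edges": len(shared_edges),
        "node_jaccard": jaccard(nodes_a, nodes_b),
        "edge_jaccard": jaccard(edges_a, edges_b),
    }
    if shared_nodes:
        ranks = {}
        for name, g in (("a", graph_a), ("b", graph_b)):
            rep = centrality(g, measures=("degree",))
            ranks[name] = float(rep.loc[sorted(shared_nodes), "degree_rank"].mean())
        out["shared_node_mean_degree_rank_a"] = ranks["a"]
        out["shared_node_mean_degree_rank_b"] = ranks["b"]
    return out


def hub_interaction_contrast(
    hub: str,
    set_a: Iterable[str],
    set_b: Iterable[str],
    interactions,
) -> Fisher2x2Result:
    """Fisher test of hub adjacency between two disjoint gene sets.

    Rows: (adjacent to hub, not adjacent); columns: (set A, set B).  Used to
    contrast e.g. genes with nonsynonymous vs synonymous SNVs against a
    candidate hub's interaction partners.
    """
    full = interactions if isinstance(interactions, nx.Graph) else edges_to_graph(interactions)
    if hub not in full:
        raise NetworkError(f"hub {hub!r} absent from interaction graph")
    a = set(set_a) - {hub}
    b = set(set_b) - {hub}
    if a & b:
        raise NetworkError("gene sets must be disjoint (after removing the hub)")
    neighbors = set(full.neighbors(hub))
    table = [
        [len(a & neighbors), len(b & neighbors)],
        [len(a - neighbors), len(b - neighbors)],
    ]
    return fisher_exact_2x2(table)
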
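"""Pseudosequence similarity graph and data-coverage hop statistics.

Nodes are distinct pseudosequences; an edge joins two nodes whose
BLOSUM62 distance is positive and at most a threshold (default 0.1).
Each node carries a ``data_mass`` attribute (its count of positive
binding records), and ``hop_coverage`` reports the fraction of nodes
within k hops of some node with data — the quantity behind statements
like "94% of alleles are adjacent to an allele with data".
"""

from __future__ import annotations

from typing import Iterable, Mapping

import networkx as nx

from .encoders import pairwise_distance_matrix

DEFAULT_D_MAX = 0.1


def build_network(
    pseudosequences: Mapping[str, str],
    d_max: float = DEFAULT_D_MAX,
    data_mass: Mapping[str, int] | None = None,
) -> nx.Graph:
    """Build the similarity graph over distinct pseudosequences.

    ``pseudosequences`` maps node id -> 34-residue string; ids must be
    unique and strings distinct (identical strings should be collapsed
    to one node upstream). Edge (i, j) exists iff 0 < d(i, j) <= d_max;
    isolated nodes are retained. ``data_mass`` attaches per-node
    positive-record counts (default 0).
    """
    ids = list(pseudosequences)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate node ids")
    seqs = [pseudosequences[i] for i in ids]
    if len(set(seqs)) != len(seqs):
        raise ValueError("pseudosequence strings must be distinct per node")
    g = nx.Graph()
    mass = data_mass or {}
    for i in ids:
        g.add_node(i, pseudosequence=pseudosequences[i],
                   data_mass=int(mass.get(i, 0)))
    d = pairwise_distance_matrix(seqs)
    n = len(ids)
    for a in range(n):
        for b in range(a + 1, n):
            if 0.0 < d[a, b] <= d_max:
                g.add_edge(ids[a], ids[b], distance=float(d[a, b]))
    return g


def hop_coverage(graph: nx.Graph, k: int) -> float:
    """Fraction of nodes within k hops of a node with data.

    A node with ``data_mass > 0`` covers itself at every k. Raises on an
    empty graph or k < 1.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    if k < 1:
        raise ValueError("k must be at least 1")
    sources = [n for n, d in graph.nodes(data=True) if d.get("data_mass", 0) > 0]
    if not sources:
        return 0.0
    # multi-source BFS truncated at depth k
    dist = {s: 0 for s in sources}
    frontier = list(sources)
    for depth in range(1, k + 1):
        nxt = []
        for u in frontier:
            for v in graph.neighbors(u):
                if v not in dist:
                    dist[v] = depth
                    nxt.append(v)
        frontier = nxt
        if not frontier:
            break
    return len(dist) / graph.number_of_nodes()


def hop_coverage_series(graph: nx.Graph, ks: Iterable[int] = (1, 2, 3)) -> dict[int, float]:
    """Coverage at several hop counts (nondecreasing in k)."""
    return {k: hop_coverage(graph, k) for k in ks}


def edge_density_by_cluster(graph: nx.Graph, cluster_id: Mapping[str, int]) -> tuple[float, float]:
    """(within-cluster, between-cluster) edge densities.

    Density is realized edges over possible pairs, computed separately
    for node pairs sharing a cluster label and pairs that do not.
    """
    nodes = list(graph.nodes)
    within_possible = between_possible = 0
    within_edges = between_edges = 0
    for i, a in enumerate(nodes):
        for b in nodes[i + 1 :]:
            same = cluster_id[a] == cluster_id[b]
            if same:
                within_possible += 1
                within_edges += graph.has_edge(a, b)
            else:
                between_possible += 1
                between_edges += graph.has_edge(a, b)
    w = within_edges / within_possible if within_possible else 0.0
    b = between_edges / between_possible if between_possible else 0.0
    return w, b


def write_edge_list(graph: nx.Graph, path) -> None:
    """Edge-list TSV: id1, id2, distance."""
    lines = ["id1\tid2\tdistance"]
    for u, v, d in graph.edges(data=True):
        lines.append(f"{u}\t{v}\t{d['distance']:.6f}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def write_node_table(graph: nx.Graph, path,
                     predicted_ppv: Mapping[str, float] | None = None) -> None:
    """Node attribute TSV: id, data_count, predicted_ppv."""
    ppv = predicted_ppv or {}
    lines = ["id\tdata_count\tpredicted_ppv"]
    for n, d in graph.nodes(data=True):
        p = ppv.get(n)
        lines.append(f"{n}\t{d.get('data_mass', 0)}\t{'' if p is None else f'{p:.4f}'}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, str(path))
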
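"""Independent brute-force oracles used to cross-check the implementations.

Each oracle deliberately takes the slow, enumerative route so that it shares
no code path with the library functions it validates.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx
import numpy as np
from sympy.utilities.iterables import multiset_partitions


def brute_force_betweenness(graph: nx.Graph, weight: str | None) -> dict:
    """Betweenness by exhaustive enumeration of all simple paths."""
    nodes = list(graph.nodes)
    cb = {v: 0.0 for v in nodes}
    for s, t in combinations(nodes, 2):
        paths = list(nx.all_simple_paths(graph, s, t))
        if not paths:
            continue
        if weight is None:
            lengths = [len(p) - 1 for p in paths]
        else:
            lengths = [
                sum(graph[u][v][weight] for u, v in zip(p, p[1:])) for p in paths
            ]
        lmin = min(lengths)
        shortest = [p for p, ln in zip(paths, lengths) if ln <= lmin + 1e-12]
        for p in shortest:
            for v in p[1:-1]:
                cb[v] += 1.0 / len(shortest)
    return cb


def exhaustive_max_modularity(graph: nx.Graph, *, null: str = "joint") -> float:
    """Maximum modularity over every set partition of the nodes (Bell-number)."""
    from ventnet.bipartite import modularity_score

    nodes = list(graph.nodes)
    best = -np.inf
    for blocks in multiset_partitions(list(range(len(nodes)))):
        partition = {}
        for label, block in enumerate(blocks):
            for idx in block:
                partition[nodes[idx]] = label
        best = max(best, modularity_score(graph, partition, null=null))
    return best


def sorensen_from_sets(rows_a, rows_b) -> float:
    """Sørensen dissimilarity via explicit set operations."""
    set_a, set_b = set(rows_a), set(rows_b)
    a = len(set_a & set_b)
    b = len(set_a - set_b)
    c = len(set_b - set_a)
    return (b + c) / (2 * a + b + c)


def spherical_law_of_cosines_km(lat1, lon1, lat2, lon2, radius=6371.0) -> float:
    """Great-circle distance by the spherical law of cosines (second formula)."""
    p1, p2 = np.radians(lat1), np.radians(lat2)
    dl = np.radians(lon2 - lon1)
    cosang = np.sin(p1) * np.sin(p2) + np.cos(p1) * np.cos(p2) * np.cos(dl)
    return radius * float(np.arccos(np.clip(cosang, -1.0, 1.0)))


def naive_pi(similarities, expected) -> float:
    """SIMPROF pi recomputed from an explicitly sorted similarity list."""
    prof = sorted(float(s) for s in similarities)
    return float(sum(abs(p - e) for p, e in zip(prof, expected)))
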
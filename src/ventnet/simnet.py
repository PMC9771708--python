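"""Sørensen similarity network: construction, percolation threshold, centrality.

Sites are nodes; each pair of sites that shares at least one species is
linked by an edge weighted with the Sørensen similarity of their assemblages,

    S_ij = 2a / (2a + b + c),      D_ij = 1 - S_ij,

where ``a`` counts species shared by the two sites and ``b``, ``c`` the
species unique to each.  Pairs with no shared species (S = 0) carry no edge
at all — absence of evidence for a connection is not an edge of weight zero.

The "weak" links of the full network are pruned at its percolation
threshold: edges are removed in descending order of dissimilarity (ties
together) and after each step the Molloy–Reed ratio kappa = <k^2>/<k> is
evaluated over *all* nodes; the threshold D_p is the dissimilarity of the
first removal step at which kappa drops below 2, the point at which a random
graph with this degree sequence loses its giant component.  The retained
network keeps the edges with D < D_p; isolated nodes are kept, never dropped.

Node importance in the thresholded network is scored with betweenness
centrality on geodesics whose edge cost is the dissimilarity (stronger
similarity = shorter path), with equal-length geodesics attributed
fractionally.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from .core import PresenceMatrix

__all__ = [
    "DissimilarityMatrix",
    "SimilarityNetwork",
    "sorensen_matrix",
    "build_similarity_network",
    "percolation_threshold",
    "apply_threshold",
    "betweenness",
    "molloy_reed_kappa",
]


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric pairwise Sørensen dissimilarity with a zero diagonal."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if vals.shape != (n, n):
            raise ValueError(f"expected {n}x{n} matrix, got {vals.shape}")
        if not np.allclose(vals, vals.T, atol=1e-12):
            raise ValueError("dissimilarity matrix is not symmetric")
        if np.abs(np.diag(vals)).max(initial=0.0) > 1e-12:
            raise ValueError("dissimilarity diagonal is not zero")
        if vals.min(initial=0.0) < -1e-12 or vals.max(initial=0.0) > 1 + 1e-12:
            raise ValueError("dissimilarity values outside [0, 1]")
        object.__setattr__(self, "values", np.clip(vals, 0.0, 1.0))

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.ids), columns=list(self.ids))

    def condensed(self) -> np.ndarray:
        """Upper-triangle values in scipy condensed order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]


@dataclass(frozen=True)
class SimilarityNetwork:
    """Weighted undirected site network (edge attrs ``similarity``/``dissimilarity``)."""

    graph: nx.Graph
    percolation: float | None = None
    thresholded: bool = False

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)


def sorensen_matrix(matrix: PresenceMatrix) -> DissimilarityMatrix:
    """Pairwise Sørensen dissimilarity D = (b+c)/(2a+b+c) between all sites.

    Vectorised as D = 1 - 2a/(r_i + r_j) with ``a`` the shared-species counts
    and ``r`` the row sums; matrix invariants guarantee r_i + r_j > 0.
    """
    X = matrix.values.astype(np.int64)
    shared = X @ X.T
    richness = X.sum(axis=1)
    denom = richness[:, None] + richness[None, :]
    D = 1.0 - 2.0 * shared / denom
    np.fill_diagonal(D, 0.0)
    return DissimilarityMatrix(ids=matrix.site_ids, values=D)


def build_similarity_network(D: DissimilarityMatrix) -> SimilarityNetwork:
    """Full (unthresholded) similarity network: an edge wherever S > 0."""
    graph = nx.Graph()
    graph.add_nodes_from(D.ids)
    n = D.n
    for i in range(n):
        for j in range(i + 1, n):
            d = D.values[i, j]
            if d < 1.0:
                graph.add_edge(
                    D.ids[i], D.ids[j], similarity=1.0 - d, dissimilarity=d
                )
    return SimilarityNetwork(graph=graph)


def molloy_reed_kappa(degrees: np.ndarray) -> float:
    """Molloy–Reed ratio <k^2>/<k> over all nodes (isolates included)."""
    degrees = np.asarray(degrees, dtype=float)
    mean_k = degrees.mean()
    if mean_k == 0:
        return 0.0
    return float((degrees**2).mean() / mean_k)


def percolation_threshold(
    D: DissimilarityMatrix, *, criterion: str = "molloy-reed"
) -> float:
    """Dissimilarity cutoff D_p at which the similarity network percolates.

    ``molloy-reed`` (default): scan edges in descending D, removing ties
    together; D_p is the D of the first removal after which kappa < 2.  If
    the intact network already has kappa < 2 the network is at percolation
    immediately and D_p is the largest edge dissimilarity present.  If kappa
    never drops below 2, D_p = 1.

    ``giant-component``: the smallest cutoff whose retained network (D < D_p)
    is a single connected component (returned as the next float above the
    connecting edge weight so the strict-< retention rule keeps that edge).
    """
    iu = np.triu_indices(D.n, k=1)
    dvals = D.values[iu]
    present = dvals < 1.0
    if not present.any():
        raise ValueError("no links to threshold: all assemblage pairs are disjoint")
    if criterion == "giant-component":
        return _giant_component_threshold(D)
    if criterion != "molloy-reed":
        raise ValueError(f"unknown percolation criterion: {criterion!r}")

    rows, cols = iu[0][present], iu[1][present]
    weights = dvals[present]
    degrees = np.zeros(D.n, dtype=np.int64)
    np.add.at(degrees, rows, 1)
    np.add.at(degrees, cols, 1)

    order = np.argsort(-weights, kind="stable")
    unique_desc = np.unique(weights)[::-1]
    if molloy_reed_kappa(degrees) < 2.0:
        return float(unique_desc[0])
    pos = 0
    for d in unique_desc:
        while pos < len(order) and weights[order[pos]] == d:
            e = order[pos]
            degrees[rows[e]] -= 1
            degrees[cols[e]] -= 1
            pos += 1
        if molloy_reed_kappa(degrees) < 2.0:
            return float(d)
    return 1.0


def _giant_component_threshold(D: DissimilarityMatrix) -> float:
    net = build_similarity_network(D)
    weights = sorted({d for _, _, d in net.graph.edges(data="dissimilarity")})
    for d in weights:
        sub = nx.Graph()
        sub.add_nodes_from(net.graph.nodes)
        sub.add_edges_from(
            (u, v)
            for u, v, dd in net.graph.edges(data="dissimilarity")
            if dd <= d
        )
        if nx.is_connected(sub):
            return float(np.nextafter(d, np.inf))
    return 1.0


def apply_threshold(net: SimilarityNetwork, d_p: float) -> SimilarityNetwork:
    """Remove edges with D >= D_p, keeping every node; label components."""
    graph = net.graph.copy()
    drop = [
        (u, v)
        for u, v, d in graph.edges(data="dissimilarity")
        if d >= d_p
    ]
    graph.remove_edges_from(drop)
    for cid, comp in enumerate(nx.connected_components(graph)):
        for node in comp:
            graph.nodes[node]["component"] = cid
    return replace(net, graph=graph, percolation=float(d_p), thresholded=True)


def betweenness(
    net: SimilarityNetwork, *, weights: str = "dissimilarity"
) -> pd.Series:
    """Unnormalised betweenness centrality of every site.

    ``weights="dissimilarity"`` (default) costs each edge by 1 - S so that
    geodesics follow chains of high similarity; ``weights="none"`` counts
    hops.  Node pairs in different components contribute nothing.
    """
    if weights == "dissimilarity":
        weight = "dissimilarity"
    elif weights in ("none", None):
        weight = None
    else:
        raise ValueError(f"unknown betweenness weight mode: {weights!r}")
    scores = nx.betweenness_centrality(net.graph, normalized=False, weight=weight)
    return pd.Series(scores, name="betweenness").reindex(list(net.graph.nodes))
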
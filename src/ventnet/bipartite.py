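"""Bipartite site–species network: modularity annealing and node cartography.

The occurrence matrix is read directly as a two-mode graph: species nodes
link to the vent-site nodes where they were recorded, by unweighted edges,
and only across the two classes.  Sites and species are then co-assigned to
modules by maximising the Newman–Girvan modularity of the joint partition,

    M = sum_s [ l_s / L - (d_s / 2L)^2 ],

where ``l_s`` counts edges with both ends in module ``s``, ``d_s`` is the
total degree of the module and ``L`` the total number of edges.  A
degree-constrained bipartite null (Barber's modularity,
``M = sum_s [ l_s/L - d_s^site d_s^species / L^2 ]``) is available through
``null="bipartite"``; the joint form is the default because modules are
expected to contain both node classes.

Maximisation uses simulated annealing: per temperature, ``f * N^2``
single-node reassignments and ``f * N`` collective proposals (module merges,
and splits refined by a short bounded local search on the module's members),
each accepted with probability min(1, exp(dM/T)); the temperature then cools
geometrically.  The best partition seen across all restarts is returned and
is additionally floored by three deterministic baselines (all singletons,
one module, connected components).  The inner loop is numba-compiled so the
published schedule defaults are affordable at the ~150-node scale of a
regional metacommunity.

Node roles follow the z–P cartography: the within-module degree z-score
``z_i`` and the participation coefficient ``P_i = 1 - sum_s (k_is/k_i)^2``
place each node in one of four quadrants split at z = 2.5 and P = 0.62
(peripheral / module hub / connector / network hub); boundary values are
assigned to the non-hub, non-connector side, and nodes whose every link
stays inside their own module (P = 0) are flagged as ultra-peripheral.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Mapping

import networkx as nx
import numpy as np
import pandas as pd
from numba import njit

from .core import PresenceMatrix

__all__ = [
    "BipartitePartition",
    "build_bipartite",
    "modularity_score",
    "anneal_partition",
    "within_module_z",
    "participation_coefficient",
    "assign_roles",
    "module_summaries",
    "module_sharing",
]

ROLE_PERIPHERAL = "Peripheral"
ROLE_MODULE_HUB = "Module hub"
ROLE_CONNECTOR = "Connector"
ROLE_NETWORK_HUB = "Network hub"

Z_THRESHOLD = 2.5
P_THRESHOLD = 0.62


def build_bipartite(matrix: PresenceMatrix) -> nx.Graph:
    """Two-mode graph: node attribute ``kind`` in {"site", "species"}."""
    overlap = set(matrix.site_ids) & set(matrix.species_ids)
    if overlap:
        raise ValueError(f"site and species ids overlap: {sorted(overlap)}")
    graph = nx.Graph()
    graph.add_nodes_from(matrix.site_ids, kind="site", bipartite=0)
    graph.add_nodes_from(matrix.species_ids, kind="species", bipartite=1)
    rows, cols = np.nonzero(matrix.values)
    graph.add_edges_from(
        (matrix.site_ids[i], matrix.species_ids[j]) for i, j in zip(rows, cols)
    )
    return graph


def modularity_score(
    graph: nx.Graph, partition: Mapping[Hashable, int], *, null: str = "joint"
) -> float:
    """Modularity of a joint partition of sites and species.

    ``null="joint"`` applies the unipartite Newman–Girvan form to the
    two-mode graph; ``null="bipartite"`` applies Barber's degree-constrained
    bipartite null.  The single-module partition scores exactly 0 under the
    joint form.
    """
    missing = [n for n in graph.nodes if n not in partition]
    if missing:
        raise ValueError(f"partition missing nodes: {missing[:5]}")
    L = graph.number_of_edges()
    if L == 0:
        raise ValueError("graph has no edges")
    labels = set(partition[n] for n in graph.nodes)
    l_s = {s: 0.0 for s in labels}
    d_site = {s: 0.0 for s in labels}
    d_spec = {s: 0.0 for s in labels}
    for u, v in graph.edges:
        if partition[u] == partition[v]:
            l_s[partition[u]] += 1.0
    for n, deg in graph.degree:
        kind = graph.nodes[n].get("kind", "site")
        if kind == "site":
            d_site[partition[n]] += deg
        else:
            d_spec[partition[n]] += deg
    if null == "joint":
        return float(
            sum(
                l_s[s] / L - ((d_site[s] + d_spec[s]) / (2.0 * L)) ** 2
                for s in labels
            )
        )
    if null == "bipartite":
        return float(
            sum(l_s[s] / L - d_site[s] * d_spec[s] / L**2 for s in labels)
        )
    raise ValueError(f"unknown modularity null: {null!r}")


# --------------------------------------------------------------------------
# Simulated-annealing kernel (numba-compiled)
# --------------------------------------------------------------------------


@njit(cache=True)
def _module_term(l, dsite, dspec, s, L, barber):
    if barber:
        return l[s] / L - dsite[s] * dspec[s] / (L * L)
    d = dsite[s] + dspec[s]
    return l[s] / L - (d / (2.0 * L)) ** 2


@njit(cache=True)
def _single_move_delta(indptr, indices, g, k, l, dsite, dspec, node_type, L, barber, i, t):
    """(dM, k_ia, k_it) for moving node i from its module to module t."""
    a = g[i]
    kia = 0
    kit = 0
    for e in range(indptr[i], indptr[i + 1]):
        gv = g[indices[e]]
        if gv == a:
            kia += 1
        elif gv == t:
            kit += 1
    ki = k[i]
    if barber:
        if node_type[i] == 0:
            dM = (kit - kia) / L - ki * (dspec[t] - dspec[a]) / (L * L)
        else:
            dM = (kit - kia) / L - ki * (dsite[t] - dsite[a]) / (L * L)
    else:
        da = dsite[a] + dspec[a]
        dt = dsite[t] + dspec[t]
        dM = (kit - kia) / L - (
            (dt + ki) ** 2 - dt * dt + (da - ki) ** 2 - da * da
        ) / (4.0 * L * L)
    return dM, kia, kit


@njit(cache=True)
def _apply_single_move(g, l, dsite, dspec, node_type, k, i, t, kia, kit):
    a = g[i]
    g[i] = t
    l[a] -= kia
    l[t] += kit
    if node_type[i] == 0:
        dsite[a] -= k[i]
        dsite[t] += k[i]
    else:
        dspec[a] -= k[i]
        dspec[t] += k[i]


@njit(cache=True)
def _anneal_kernel(
    indptr,
    indices,
    node_type,
    L,
    barber,
    seed,
    t_initial,
    cooling,
    t_min,
    f,
    stall_limit,
    split_sweeps,
):
    np.random.seed(seed)
    N = node_type.size
    g = np.arange(N, dtype=np.int64)
    k = np.empty(N, dtype=np.int64)
    for i in range(N):
        k[i] = indptr[i + 1] - indptr[i]
    l = np.zeros(N, dtype=np.float64)
    dsite = np.zeros(N, dtype=np.float64)
    dspec = np.zeros(N, dtype=np.float64)
    for i in range(N):
        if node_type[i] == 0:
            dsite[g[i]] += k[i]
        else:
            dspec[g[i]] += k[i]
    M = 0.0
    for s in range(N):
        M += _module_term(l, dsite, dspec, s, L, barber)

    # Calibrate the initial temperature so that ~95% of random single-node
    # moves from the starting state would be accepted.
    T = t_initial
    if T <= 0.0:
        worst = 0.0
        negs = np.zeros(200, dtype=np.float64)
        nneg = 0
        for _ in range(200):
            i = np.random.randint(N)
            t = np.random.randint(N)
            if t == g[i]:
                continue
            dM, _, _ = _single_move_delta(
                indptr, indices, g, k, l, dsite, dspec, node_type, L, barber, i, t
            )
            if dM < 0.0 and nneg < negs.size:
                negs[nneg] = -dM
                nneg += 1
        if nneg > 0:
            sub = np.sort(negs[:nneg])
            worst = sub[min(nneg - 1, int(0.95 * nneg))]
        if worst <= 0.0:
            T = 0.05
        else:
            T = worst / 0.0513  # exp(-worst/T) = 0.95

    best_M = M
    best_g = g.copy()
    n_single = int(f * N * N)
    n_collective = int(f * N)
    stall = 0
    while T > t_min:
        improved_M_at_start = best_M
        n_worse_proposed = 0
        n_worse_accepted = 0
        for _ in range(n_single):
            i = np.random.randint(N)
            t = np.random.randint(N)
            if t == g[i]:
                continue
            dM, kia, kit = _single_move_delta(
                indptr, indices, g, k, l, dsite, dspec, node_type, L, barber, i, t
            )
            accept = dM >= 0.0
            if not accept:
                n_worse_proposed += 1
                if np.random.random() < np.exp(dM / T):
                    accept = True
                    n_worse_accepted += 1
            if accept:
                _apply_single_move(g, l, dsite, dspec, node_type, k, i, t, kia, kit)
                M += dM
                if M > best_M:
                    best_M = M
                    best_g[:] = g
        for _ in range(n_collective):
            if np.random.random() < 0.5:
                M = _merge_move(
                    indptr, indices, g, k, l, dsite, dspec, node_type, L, barber, M, T
                )
            else:
                M = _split_move(
                    indptr,
                    indices,
                    g,
                    k,
                    l,
                    dsite,
                    dspec,
                    node_type,
                    L,
                    barber,
                    M,
                    T,
                    split_sweeps,
                )
            if M > best_M:
                best_M = M
                best_g[:] = g
        # Early stop only once the chain is frozen: no new best for
        # stall_limit consecutive temperatures while essentially no
        # worsening move is being accepted any more.
        frozen = n_worse_accepted <= 0.02 * n_worse_proposed
        if best_M > improved_M_at_start + 1e-12:
            stall = 0
        elif frozen:
            stall += 1
            if stall >= stall_limit:
                break
        T *= cooling
    return best_g, best_M


@njit(cache=True)
def _merge_move(indptr, indices, g, k, l, dsite, dspec, node_type, L, barber, M, T):
    N = g.size
    i = np.random.randint(N)
    j = np.random.randint(N)
    a = g[i]
    b = g[j]
    if a == b:
        return M
    l_ab = 0.0
    for v in range(N):
        if g[v] == a:
            for e in range(indptr[v], indptr[v + 1]):
                if g[indices[e]] == b:
                    l_ab += 1.0
    if barber:
        dM = l_ab / L - (dsite[a] * dspec[b] + dsite[b] * dspec[a]) / (L * L)
    else:
        da = dsite[a] + dspec[a]
        db = dsite[b] + dspec[b]
        dM = l_ab / L - da * db / (2.0 * L * L)
    if dM >= 0.0 or np.random.random() < np.exp(dM / T):
        for v in range(N):
            if g[v] == b:
                g[v] = a
        l[a] += l[b] + l_ab
        l[b] = 0.0
        dsite[a] += dsite[b]
        dsite[b] = 0.0
        dspec[a] += dspec[b]
        dspec[b] = 0.0
        return M + dM
    return M


@njit(cache=True)
def _split_move(
    indptr, indices, g, k, l, dsite, dspec, node_type, L, barber, M, T, split_sweeps
):
    N = g.size
    i = np.random.randint(N)
    a = g[i]
    n_members = 0
    for v in range(N):
        if g[v] == a:
            n_members += 1
    if n_members < 2:
        return M
    # Locate an unused module label for the second half.
    b = -1
    for s in range(N):
        if dsite[s] + dspec[s] == 0.0:
            b = s
            break
    if b < 0:
        return M
    members = np.empty(n_members, dtype=np.int64)
    idx = 0
    for v in range(N):
        if g[v] == a:
            members[idx] = v
            idx += 1
    term_before = _module_term(l, dsite, dspec, a, L, barber)
    saved_la = l[a]
    saved_dsite_a = dsite[a]
    saved_dspec_a = dspec[a]
    # Random bisection followed by a short greedy refinement between the two
    # halves (the bounded inner search of the split device).
    for v in members:
        if np.random.random() < 0.5:
            g[v] = b
    _recount_pair(indptr, indices, g, k, l, dsite, dspec, node_type, a, b)
    for _ in range(split_sweeps):
        moved = False
        for v in members:
            t = b if g[v] == a else a
            dM, kia, kit = _single_move_delta(
                indptr, indices, g, k, l, dsite, dspec, node_type, L, barber, v, t
            )
            if dM > 1e-15:
                _apply_single_move(g, l, dsite, dspec, node_type, k, v, t, kia, kit)
                moved = True
        if not moved:
            break
    term_after = (
        _module_term(l, dsite, dspec, a, L, barber)
        + _module_term(l, dsite, dspec, b, L, barber)
    )
    dM_total = term_after - term_before
    if dM_total >= 0.0 or np.random.random() < np.exp(dM_total / T):
        return M + dM_total
    for v in members:
        g[v] = a
    l[a] = saved_la
    l[b] = 0.0
    dsite[a] = saved_dsite_a
    dsite[b] = 0.0
    dspec[a] = saved_dspec_a
    dspec[b] = 0.0
    return M


@njit(cache=True)
def _recount_pair(indptr, indices, g, k, l, dsite, dspec, node_type, a, b):
    """Recompute l, dsite, dspec for the two modules a and b from scratch."""
    la = 0.0
    lb = 0.0
    dsa = 0.0
    dsb = 0.0
    dpa = 0.0
    dpb = 0.0
    N = g.size
    for v in range(N):
        gv = g[v]
        if gv != a and gv != b:
            continue
        for e in range(indptr[v], indptr[v + 1]):
            w = indices[e]
            if g[w] == gv:
                if gv == a:
                    la += 0.5
                else:
                    lb += 0.5
        if node_type[v] == 0:
            if gv == a:
                dsa += k[v]
            else:
                dsb += k[v]
        else:
            if gv == a:
                dpa += k[v]
            else:
                dpb += k[v]
    l[a] = la
    l[b] = lb
    dsite[a] = dsa
    dsite[b] = dsb
    dspec[a] = dpa
    dspec[b] = dpb


# --------------------------------------------------------------------------
# Public annealing interface
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class BipartitePartition:
    """Joint module assignment for sites and species with cartography."""

    partition: dict  # node -> module label (0..K-1)
    modularity: float
    null: str
    z: pd.Series = field(repr=False)
    participation: pd.Series = field(repr=False)
    roles: pd.Series = field(repr=False)
    metadata: dict = field(default_factory=dict, repr=False)

    @property
    def n_modules(self) -> int:
        return len(set(self.partition.values()))

    def members(self, graph: nx.Graph, module: int, kind: str | None = None) -> list:
        nodes = [n for n, m in self.partition.items() if m == module]
        if kind is not None:
            nodes = [n for n in nodes if graph.nodes[n]["kind"] == kind]
        return nodes


def anneal_partition(
    graph: nx.Graph,
    *,
    seed: int = 0,
    restarts: int = 10,
    cooling: float = 0.995,
    moves_factor: float = 1.0,
    t_initial: float = -1.0,
    t_min: float = 1e-6,
    stall_limit: int = 10,
    split_sweeps: int = 3,
    null: str = "joint",
) -> BipartitePartition:
    """Best-of-restarts simulated-annealing modularity partition.

    ``t_initial <= 0`` calibrates the starting temperature from a probe of
    random moves; each restart draws an independent seed from ``seed``.  The
    returned modularity is never below that of the singleton, single-module
    or connected-component baselines.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    if not 0.0 < cooling < 1.0:
        raise ValueError("cooling factor must lie in (0, 1)")
    if null not in ("joint", "bipartite"):
        raise ValueError(f"unknown modularity null: {null!r}")
    nodes = list(graph.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    node_type = np.array(
        [0 if graph.nodes[n].get("kind", "site") == "site" else 1 for n in nodes],
        dtype=np.int8,
    )
    adj = [[] for _ in nodes]
    for u, v in graph.edges:
        adj[index[u]].append(index[v])
        adj[index[v]].append(index[u])
    indptr = np.zeros(len(nodes) + 1, dtype=np.int64)
    for i, nb in enumerate(adj):
        indptr[i + 1] = indptr[i] + len(nb)
    indices = np.concatenate([np.array(nb, dtype=np.int64) for nb in adj]) if graph.number_of_edges() else np.zeros(0, dtype=np.int64)
    L = float(graph.number_of_edges())
    if L == 0:
        raise ValueError("graph has no edges")
    barber = null == "bipartite"

    child_seeds = np.random.SeedSequence(seed).generate_state(restarts) % (2**31 - 1)
    best_g = None
    best_M = -np.inf
    for r in range(restarts):
        g, M = _anneal_kernel(
            indptr,
            indices,
            node_type,
            L,
            barber,
            int(child_seeds[r]),
            float(t_initial),
            float(cooling),
            float(t_min),
            float(moves_factor),
            int(stall_limit),
            int(split_sweeps),
        )
        if M > best_M:
            best_M = M
            best_g = g

    partition = {n: int(best_g[index[n]]) for n in nodes}
    # Deterministic baselines floor the stochastic search.
    baselines = [
        {n: i for i, n in enumerate(nodes)},
        {n: 0 for n in nodes},
        {
            n: cid
            for cid, comp in enumerate(nx.connected_components(graph))
            for n in comp
        },
    ]
    best_partition, best_score = partition, modularity_score(graph, partition, null=null)
    for base in baselines:
        score = modularity_score(graph, base, null=null)
        if score > best_score + 1e-12:
            best_partition, best_score = base, score

    relabel: dict[int, int] = {}
    for n in nodes:
        m = best_partition[n]
        if m not in relabel:
            relabel[m] = len(relabel)
    final = {n: relabel[best_partition[n]] for n in nodes}
    z = within_module_z(graph, final)
    p = participation_coefficient(graph, final)
    roles = assign_roles(z, p)
    return BipartitePartition(
        partition=final,
        modularity=float(best_score),
        null=null,
        z=z,
        participation=p,
        roles=roles,
        metadata={
            "seed": seed,
            "restarts": restarts,
            "cooling": cooling,
            "moves_factor": moves_factor,
            "restart_seeds": [int(s) for s in child_seeds],
            "kernel_best_modularity": float(best_M),
        },
    )


# --------------------------------------------------------------------------
# Cartography
# --------------------------------------------------------------------------


def _within_module_degrees(graph: nx.Graph, partition: Mapping) -> pd.Series:
    kappa = {}
    for n in graph.nodes:
        m = partition[n]
        kappa[n] = sum(1 for nb in graph.neighbors(n) if partition[nb] == m)
    return pd.Series(kappa, dtype=float)


def within_module_z(graph: nx.Graph, partition: Mapping) -> pd.Series:
    """z-score of each node's internal link count within its module.

    Uses the population standard deviation over the module's members; a
    module whose members all have the same internal degree gives z = 0.
    """
    kappa = _within_module_degrees(graph, partition)
    labels = pd.Series({n: partition[n] for n in graph.nodes})
    z = pd.Series(0.0, index=kappa.index)
    for m, members in labels.groupby(labels).groups.items():
        vals = kappa.loc[list(members)]
        sigma = vals.std(ddof=0)
        if sigma > 0:
            z.loc[list(members)] = (vals - vals.mean()) / sigma
    return z.rename("z")


def participation_coefficient(graph: nx.Graph, partition: Mapping) -> pd.Series:
    """P_i = 1 - sum_s (k_is / k_i)^2; zero when all links stay home."""
    p = {}
    for n in graph.nodes:
        k_i = graph.degree(n)
        counts: dict = {}
        for nb in graph.neighbors(n):
            m = partition[nb]
            counts[m] = counts.get(m, 0) + 1
        p[n] = 1.0 - sum((c / k_i) ** 2 for c in counts.values()) if k_i else 0.0
    return pd.Series(p, name="participation")


def assign_roles(z: pd.Series, participation: pd.Series) -> pd.Series:
    """Quadrant role labels with boundary values assigned to the modest side."""
    roles = {}
    for n in z.index:
        hub = z[n] > Z_THRESHOLD
        connector = participation[n] > P_THRESHOLD
        if hub and connector:
            roles[n] = ROLE_NETWORK_HUB
        elif hub:
            roles[n] = ROLE_MODULE_HUB
        elif connector:
            roles[n] = ROLE_CONNECTOR
        else:
            roles[n] = ROLE_PERIPHERAL
    return pd.Series(roles, name="role")


def ultra_periphery(participation: pd.Series) -> pd.Series:
    """Boolean flag: every one of the node's links stays inside its module."""
    return (participation == 0.0).rename("ultra_periphery")


def module_summaries(graph: nx.Graph, partition: Mapping) -> pd.DataFrame:
    """Per-module membership and endemism summary.

    A species is endemic to a module when every site it links to belongs to
    that module (regardless of the species node's own label).
    """
    modules = sorted(set(partition.values()))
    rows = []
    for m in modules:
        sites = [
            n for n in graph.nodes
            if partition[n] == m and graph.nodes[n]["kind"] == "site"
        ]
        species = [
            n for n in graph.nodes
            if partition[n] == m and graph.nodes[n]["kind"] == "species"
        ]
        endemics = [
            sp
            for sp in species
            if all(partition[site] == m for site in graph.neighbors(sp))
        ]
        rows.append(
            {
                "module": m,
                "n_sites": len(sites),
                "n_species": len(species),
                "n_endemic_species": len(endemics),
                "endemic_fraction": (
                    len(endemics) / len(species) if species else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)


def module_sharing(graph: nx.Graph, partition: Mapping) -> pd.DataFrame:
    """Species shared between module pairs, tabulated two ways.

    ``n_outreach`` (ordered pair m -> m'): species assigned to module m with
    at least one link to a site of module m'.  ``n_shared`` (unordered,
    repeated on both orderings): species with links to sites of both m and
    m', regardless of the species' own module label.
    """
    modules = sorted(set(partition.values()))
    species = [n for n in graph.nodes if graph.nodes[n]["kind"] == "species"]
    site_modules = {
        sp: {partition[site] for site in graph.neighbors(sp)} for sp in species
    }
    rows = []
    for m in modules:
        for m2 in modules:
            if m == m2:
                continue
            outreach = sum(
                1 for sp in species if partition[sp] == m and m2 in site_modules[sp]
            )
            shared = sum(
                1
                for sp in species
                if m in site_modules[sp] and m2 in site_modules[sp]
            )
            rows.append(
                {
                    "module": m,
                    "other_module": m2,
                    "n_outreach": outreach,
                    "n_shared": shared,
                }
            )
    return pd.DataFrame(rows)
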
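"""SIMPROF: similarity-profile permutation tests over a UPGMA dendrogram.

Hierarchical clustering alone always yields a tree, whether or not the data
contain real multivariate structure.  The similarity-profile (SIMPROF) test
guards against over-interpretation: for a putative group of sites it compares
the observed profile — the n(n-1)/2 pairwise Sørensen similarities sorted
ascending — with the mean profile expected when each species column is
permuted independently across the group's sites, via the statistic

    pi = sum_k | s_k - sbar_k |.

Large pi means the group's similarities are more spread (some pairs much more
alike than chance) than a structureless assemblage would produce.  Testing
proceeds top-down from the dendrogram root: a significant node is opened and
its children tested in turn; a non-significant node terminates as one flat
SIMPROF group.  Groups of fewer than three sites are untestable (their
profile holds at most one value) and terminate as groups.

No multiplicity correction is applied across the sequential tests; the
hierarchical stopping rule is the method's standard behaviour.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .core import PresenceMatrix
from .simnet import DissimilarityMatrix, sorensen_matrix

__all__ = [
    "Dendrogram",
    "SimprofResult",
    "average_linkage_dendrogram",
    "sorted_similarity_profile",
    "simprof_pi",
    "simprof_test",
    "simprof_partition",
]


@dataclass(frozen=True)
class Dendrogram:
    """Agglomerative merge tree over sites (scipy linkage encoding)."""

    ids: tuple[str, ...]
    linkage: np.ndarray = field(repr=False)
    method: str = "average"

    def __post_init__(self) -> None:
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-12):
            raise ValueError("merge heights must be non-decreasing")

    def root(self) -> hierarchy.ClusterNode:
        return hierarchy.to_tree(self.linkage)

    def to_newick(self) -> str:
        """Newick string with branch lengths derived from merge heights."""

        def recurse(node: hierarchy.ClusterNode, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.ids[node.id]}:{length:.10g}"
            left = recurse(node.left, node.dist)
            right = recurse(node.right, node.dist)
            return f"({left},{right}):{length:.10g}"

        root = self.root()
        return recurse(root, root.dist) + ";"


@dataclass(frozen=True)
class SimprofResult:
    """Flat SIMPROF grouping plus the per-node permutation tests behind it."""

    groups: pd.Series  # site_id -> group number (1-based, in dendrogram order)
    tests: pd.DataFrame  # one row per tested node: size, pi, p, significant
    alpha: float

    @property
    def n_groups(self) -> int:
        return int(self.groups.nunique())


def average_linkage_dendrogram(
    D: DissimilarityMatrix, *, method: str = "average"
) -> Dendrogram:
    """Group-average (UPGMA) agglomeration of the Sørensen dissimilarities.

    ``method`` may also be ``complete`` or ``single``; group-average is the
    convention of the SIMPROF literature and the default throughout.
    """
    if D.n < 2:
        raise ValueError("need at least two sites to build a dendrogram")
    Z = hierarchy.linkage(D.condensed(), method=method)
    return Dendrogram(ids=D.ids, linkage=Z, method=method)


def sorted_similarity_profile(values: np.ndarray) -> np.ndarray:
    """Ascending pairwise Sørensen similarities within one group of sites."""
    X = np.asarray(values, dtype=np.int64)
    shared = X @ X.T
    richness = X.sum(axis=1)
    denom = richness[:, None] + richness[None, :]
    with np.errstate(invalid="ignore", divide="ignore"):
        S = np.where(denom > 0, 2.0 * shared / denom, 0.0)
    iu = np.triu_indices(len(X), k=1)
    return np.sort(S[iu])


def simprof_pi(profile: np.ndarray, expected_profile: np.ndarray) -> float:
    """pi = sum of absolute deviations between observed and expected profiles."""
    profile = np.asarray(profile, dtype=float)
    expected_profile = np.asarray(expected_profile, dtype=float)
    if profile.shape != expected_profile.shape:
        raise ValueError("profile and expected profile differ in length")
    if profile.size < 1:
        raise ValueError("untestable group: fewer than 2 members")
    return float(np.abs(profile - expected_profile).sum())


def simprof_test(
    values: np.ndarray,
    rng: np.random.Generator,
    *,
    n_perm_expected: int = 1000,
    n_perm_null: int = 999,
) -> tuple[float, float]:
    """Permutation test of one group; returns (pi_observed, p).

    The expected profile is the mean sorted profile over ``n_perm_expected``
    permutations in which every species column is shuffled independently
    across the group's sites; ``n_perm_null`` further permutations provide
    the null pi distribution, and p = (1 + #{pi_null >= pi_obs}) /
    (1 + n_perm_null).
    """
    X = np.asarray(values, dtype=np.int8)
    if len(X) < 3:
        raise ValueError("untestable group: SIMPROF needs at least 3 sites")
    if n_perm_expected < 1 or n_perm_null < 1:
        raise ValueError("permutation counts must be at least 1")
    observed = sorted_similarity_profile(X)
    expected = np.zeros_like(observed)
    for _ in range(n_perm_expected):
        expected += sorted_similarity_profile(rng.permuted(X, axis=0))
    expected /= n_perm_expected
    pi_obs = simprof_pi(observed, expected)
    exceed = 0
    for _ in range(n_perm_null):
        pi_null = simprof_pi(
            sorted_similarity_profile(rng.permuted(X, axis=0)), expected
        )
        if pi_null >= pi_obs - 1e-12:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm_null)
    return pi_obs, p


def simprof_partition(
    matrix: PresenceMatrix,
    tree: Dendrogram | None = None,
    *,
    n_perm_expected: int = 1000,
    n_perm_null: int = 999,
    alpha: float = 0.05,
    seed: int = 0,
) -> SimprofResult:
    """Top-down SIMPROF traversal yielding a flat partition of the sites.

    A single seeded RNG stream is consumed in pre-order traversal so results
    are reproducible for a given (matrix, tree, seed).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    if tree is None:
        tree = average_linkage_dendrogram(sorensen_matrix(matrix))
    if tuple(tree.ids) != tuple(matrix.site_ids):
        raise ValueError("dendrogram was not built from this matrix's sites")
    rng = np.random.default_rng(seed)
    records: list[dict] = []
    group_leaf_sets: list[list[int]] = []

    def visit(node: hierarchy.ClusterNode) -> None:
        leaves = node.pre_order(lambda x: x.id)
        if len(leaves) < 3:
            group_leaf_sets.append(leaves)
            return
        pi_obs, p = simprof_test(
            matrix.values[leaves],
            rng,
            n_perm_expected=n_perm_expected,
            n_perm_null=n_perm_null,
        )
        significant = p <= alpha
        records.append(
            {
                "size": len(leaves),
                "height": node.dist,
                "pi": pi_obs,
                "p": p,
                "significant": significant,
            }
        )
        if significant:
            visit(node.left)
            visit(node.right)
        else:
            group_leaf_sets.append(leaves)

    visit(tree.root())
    # Number groups by their leftmost leaf in dendrogram order.
    group_leaf_sets.sort(key=lambda leaves: min(leaves))
    assignment: dict[str, int] = {}
    for gid, leaves in enumerate(group_leaf_sets, start=1):
        for leaf in leaves:
            assignment[matrix.site_ids[leaf]] = gid
    groups = pd.Series(
        [assignment[s] for s in matrix.site_ids],
        index=list(matrix.site_ids),
        name="simprof_group",
    )
    tests = pd.DataFrame(
        records, columns=["size", "height", "pi", "p", "significant"]
    )
    return SimprofResult(groups=groups, tests=tests, alpha=alpha)
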
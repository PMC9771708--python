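"""Spatial and environmental drivers of assemblage dissimilarity.

Space enters the analysis through distance-based Moran's Eigenvector Maps
(dbMEM): the great-circle distance matrix is truncated at a threshold ``t``
(distances beyond ``t`` are replaced by ``4t``), Gower-centred, and
eigendecomposed; the eigenvectors with positive eigenvalues form an
orthogonal spatial basis whose leading vectors describe broad gradients and
whose trailing vectors describe fine structure.  Two bases are built: a
*broad-scale* basis truncated at the longest minimum-spanning-tree edge (the
smallest threshold keeping every site connected) and a *fine-scale* basis
truncated just below the distance that connects the Okinawa Trough sites to
the rest of the region, so that under it the trough is spatially decoupled.

The contribution of environment (depth, tectonic setting) and the two
spatial bases to beta-diversity is quantified by variance partitioning on a
distance-based RDA: the response is the set of positive principal-coordinate
axes of the Sørensen dissimilarity matrix, each predictor-set union is fit
by multivariate least squares, R^2 is adjusted with Ezekiel's formula
``R2adj = 1 - (1 - R2)(n - 1)/(n - m - 1)``, and unique/shared fractions are
recovered by inclusion–exclusion.  Individual fractions may legitimately be
negative; the seven fractions sum to the adjusted R^2 of the full model.

Module membership is related to the same predictors by a redundancy
analysis (module indicators as the multivariate response) and a one-way
MANOVA with module as the factor.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import eigh
from scipy.sparse.csgraph import minimum_spanning_tree

from .simnet import DissimilarityMatrix

__all__ = [
    "GeodesicMatrix",
    "DbmemBasis",
    "VarianceFractions",
    "geodesic_matrix",
    "dbmem_basis",
    "make_scale_thresholds",
    "env_design",
    "pcoa_axes",
    "adjusted_r2",
    "variance_partition",
    "membership_rda",
    "manova_modules",
    "moran_i",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class GeodesicMatrix:
    """Pairwise great-circle distances between sites, in kilometres."""

    ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values.copy(), index=list(self.ids), columns=list(self.ids))


@dataclass(frozen=True)
class DbmemBasis:
    """Orthogonal, centred spatial eigenvector basis at one scale."""

    ids: tuple[str, ...]
    truncation_km: float
    eigenvalues: np.ndarray = field(repr=False)
    scores: pd.DataFrame = field(repr=False)  # sites x eigenvectors
    scale: str = "broad"

    @property
    def n_vectors(self) -> int:
        return self.scores.shape[1]


def geodesic_matrix(meta: pd.DataFrame) -> GeodesicMatrix:
    """Haversine great-circle distances (Earth radius 6371.0 km)."""
    lat = np.radians(meta["latitude"].to_numpy(dtype=float))
    lon = np.radians(meta["longitude"].to_numpy(dtype=float))
    dlat = lat[:, None] - lat[None, :]
    dlon = lon[:, None] - lon[None, :]
    h = (
        np.sin(dlat / 2.0) ** 2
        + np.cos(lat)[:, None] * np.cos(lat)[None, :] * np.sin(dlon / 2.0) ** 2
    )
    d = 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))
    np.fill_diagonal(d, 0.0)
    return GeodesicMatrix(ids=tuple(meta["site_id"]), values=d)


def dbmem_basis(
    G: GeodesicMatrix,
    truncation_km: float,
    *,
    scale: str = "broad",
    retain: str = "positive-moran",
) -> DbmemBasis:
    """dbMEM basis from the truncated distance matrix.

    Distances above the truncation are replaced by four times the truncation;
    the resulting matrix is Gower-centred and eigendecomposed, and retained
    eigenvectors are scaled by the square root of their eigenvalue.  Column
    signs are fixed deterministically.

    ``retain="positive-moran"`` (default) keeps eigenvectors with eigenvalue
    > 1e-9 *and* Moran's I above its null expectation -1/(n-1) under the
    within-threshold connectivity — the standard dbMEM convention, which
    models positive spatial autocorrelation and keeps the basis small enough
    for adjusted-R^2 work at metacommunity sample sizes.
    ``retain="positive-eigenvalue"`` keeps every eigenvector with eigenvalue
    > 1e-9.
    """
    if retain not in ("positive-moran", "positive-eigenvalue"):
        raise ValueError(f"unknown retention rule: {retain!r}")
    if truncation_km <= 0:
        raise ValueError("truncation must be positive")
    D = G.values
    n = D.shape[0]
    offdiag = D[~np.eye(n, dtype=bool)]
    if (offdiag > truncation_km).all():
        raise ValueError(
            f"threshold {truncation_km} km isolates all sites "
            f"(smallest inter-site distance {offdiag.min():.1f} km)"
        )
    Dstar = np.where(D <= truncation_km, D, 4.0 * truncation_km)
    np.fill_diagonal(Dstar, 0.0)
    A = -0.5 * Dstar**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    # strictly positive eigenvalues; the tolerance is relative because the
    # spectrum scales with the squared truncation distance
    keep = eigval > 1e-9 * max(np.abs(eigval).max(), 1.0)
    eigval, eigvec = eigval[keep], eigvec[:, keep]
    if retain == "positive-moran" and eigvec.shape[1]:
        W = ((D <= truncation_km) & ~np.eye(n, dtype=bool)).astype(float)
        num = np.einsum("ij,ik,jk->k", W, eigvec, eigvec)
        den = (eigvec**2).sum(axis=0)
        I = n / W.sum() * num / den
        keep2 = I > -1.0 / (n - 1)
        eigval, eigvec = eigval[keep2], eigvec[:, keep2]
    # re-centre: eigh lets near-zero eigenvectors rotate slightly with the
    # exact-zero constant eigenvector when the spectral gap is tiny
    eigvec = eigvec - eigvec.mean(axis=0)
    scores = eigvec * np.sqrt(eigval)
    # Deterministic sign: the entry of largest magnitude is positive.
    for j in range(scores.shape[1]):
        pivot = np.argmax(np.abs(scores[:, j]))
        if scores[pivot, j] < 0:
            scores[:, j] = -scores[:, j]
    frame = pd.DataFrame(
        scores,
        index=list(G.ids),
        columns=[f"{scale}_mem{j + 1}" for j in range(scores.shape[1])],
    )
    return DbmemBasis(
        ids=G.ids,
        truncation_km=float(truncation_km),
        eigenvalues=eigval,
        scores=frame,
        scale=scale,
    )


def make_scale_thresholds(
    G: GeodesicMatrix,
    meta: pd.DataFrame,
    okinawa_label: "str | set[str] | Sequence[str]" = "Okinawa Trough",
) -> tuple[float, float]:
    """(t_fine, t_broad) truncation distances in km.

    ``t_broad`` is the longest edge of the minimum spanning tree (the
    standard dbMEM default guaranteeing a fully connected spatial graph);
    ``t_fine`` sits just below the smallest distance connecting any
    Okinawa-Trough site to any site outside it, so the fine basis treats the
    trough as spatially self-contained.
    """
    if "region" not in meta.columns:
        raise ValueError("metadata has no 'region' column")
    labels = {okinawa_label} if isinstance(okinawa_label, str) else set(okinawa_label)
    meta = meta.loc[list(G.ids)]
    in_group = meta["region"].isin(labels).to_numpy()
    if not in_group.any():
        raise ValueError(f"no sites labelled {sorted(labels)!r}")
    if in_group.all():
        raise ValueError(f"all sites labelled {sorted(labels)!r}; no outside sites")
    mst = minimum_spanning_tree(G.values)
    t_broad = float(mst.toarray().max())
    cross = G.values[np.ix_(in_group, ~in_group)]
    t_fine = float(cross.min() * (1.0 - 1e-6))
    return t_fine, t_broad


def env_design(meta: pd.DataFrame) -> pd.DataFrame:
    """Environmental predictor table: standardized depth + tectonic dummies."""
    depth = meta["depth_m"].astype(float)
    out = pd.DataFrame(index=meta.index)
    out["depth"] = (depth - depth.mean()) / depth.std(ddof=1)
    dummies = pd.get_dummies(meta["tectonic_setting"], prefix="tect", drop_first=True)
    for col in dummies.columns:
        out[col.replace(" ", "_")] = dummies[col].astype(float)
    return out


def pcoa_axes(D: DissimilarityMatrix) -> pd.DataFrame:
    """Positive-eigenvalue principal-coordinate axes of the dissimilarity."""
    n = D.n
    A = -0.5 * D.values**2
    J = np.eye(n) - np.ones((n, n)) / n
    B = J @ A @ J
    B = (B + B.T) / 2.0
    eigval, eigvec = eigh(B)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    keep = eigval > 1e-9 * max(np.abs(eigval).max(), 1.0)
    scores = eigvec[:, keep] * np.sqrt(eigval[keep])
    return pd.DataFrame(
        scores,
        index=list(D.ids),
        columns=[f"pco{j + 1}" for j in range(int(keep.sum()))],
    )


def _multivariate_r2(Y: np.ndarray, X: np.ndarray) -> float:
    """R^2 of a multivariate least-squares fit with intercept."""
    Yc = Y - Y.mean(axis=0)
    Xc = X - X.mean(axis=0)
    sst = float((Yc**2).sum())
    if sst == 0:
        raise ValueError("response has no variance")
    if Xc.shape[1] == 0:
        return 0.0
    beta, *_ = np.linalg.lstsq(Xc, Yc, rcond=None)
    resid = Yc - Xc @ beta
    return 1.0 - float((resid**2).sum()) / sst


def adjusted_r2(r2: float, n: int, m: int) -> float:
    """Ezekiel's adjustment: 1 - (1 - R^2)(n - 1)/(n - m - 1)."""
    if n - m - 1 <= 0:
        raise ValueError(
            f"over-parameterized set: {m} predictors for {n} observations"
        )
    return 1.0 - (1.0 - r2) * (n - 1) / (n - m - 1)


@dataclass(frozen=True)
class VarianceFractions:
    """Inclusion–exclusion decomposition of adjusted R^2 over three sets.

    Keys of ``fractions``: unique fractions ``env``, ``fine``, ``broad``;
    pairwise intersections ``env&fine``, ``env&broad``, ``fine&broad``; the
    triple intersection ``env&fine&broad``; plus ``residual``.
    """

    fractions: dict
    union_adjusted_r2: dict
    n: int

    @property
    def total_explained(self) -> float:
        return float(sum(v for k, v in self.fractions.items() if k != "residual"))


def variance_partition(
    D: DissimilarityMatrix,
    env: pd.DataFrame,
    fine: DbmemBasis,
    broad: DbmemBasis,
) -> VarianceFractions:
    """Partition beta-diversity variance over environment and the two scales."""
    ids = list(D.ids)
    Y = pcoa_axes(D).to_numpy()
    blocks = {
        "env": env.loc[ids].to_numpy(dtype=float),
        "fine": fine.scores.loc[ids].to_numpy(dtype=float),
        "broad": broad.scores.loc[ids].to_numpy(dtype=float),
    }
    n = len(ids)
    names = ("env", "fine", "broad")
    adj: dict[frozenset, float] = {frozenset(): 0.0}
    for r in range(1, 4):
        for combo in itertools.combinations(names, r):
            X = np.hstack([blocks[b] for b in combo])
            m = X.shape[1]
            adj[frozenset(combo)] = adjusted_r2(_multivariate_r2(Y, X), n, m)

    A = lambda *sets: adj[frozenset(sets)]  # noqa: E731
    full = A("env", "fine", "broad")
    a = full - A("fine", "broad")
    b = full - A("env", "broad")
    c = full - A("env", "fine")
    d = full - A("broad") - a - b
    e = full - A("env") - b - c
    f = full - A("fine") - a - c
    g = full - a - b - c - d - e - f
    fractions = {
        "env": a,
        "fine": b,
        "broad": c,
        "env&fine": d,
        "fine&broad": e,
        "env&broad": f,
        "env&fine&broad": g,
        "residual": 1.0 - full,
    }
    return VarianceFractions(
        fractions=fractions,
        union_adjusted_r2={"+".join(sorted(k)): v for k, v in adj.items() if k},
        n=n,
    )


def membership_rda(
    labels: pd.Series, env: pd.DataFrame, broad: DbmemBasis
) -> dict:
    """Redundancy analysis of module membership on environment + broad space.

    Module membership is dummy-coded as the multivariate response; returns
    the raw constrained proportion (explained / total variance) and its
    Ezekiel-adjusted counterpart.
    """
    labels = labels.astype(str)
    if labels.nunique() < 2:
        raise ValueError("membership RDA needs at least two modules")
    ids = list(labels.index)
    Y = pd.get_dummies(labels).astype(float).to_numpy()
    X = np.hstack(
        [env.loc[ids].to_numpy(dtype=float), broad.scores.loc[ids].to_numpy(dtype=float)]
    )
    r2 = _multivariate_r2(Y, X)
    return {
        "proportion": float(r2),
        "proportion_adjusted": float(adjusted_r2(r2, len(ids), X.shape[1])),
        "n_predictors": int(X.shape[1]),
        "n": len(ids),
    }


def manova_modules(
    labels: pd.Series, env: pd.DataFrame, broad: DbmemBasis
) -> pd.DataFrame:
    """One-way MANOVA: module as factor; depth, tectonic and broad MEMs as responses.

    Returns Wilks' lambda with its Rao F approximation and p-value, one row
    per response block (all responses jointly plus each block separately).
    """
    from statsmodels.multivariate.manova import MANOVA

    labels = labels.astype(str)
    counts = labels.value_counts()
    if len(counts) < 2:
        raise ValueError("MANOVA needs at least two modules")
    ids = list(labels.index)
    resp_blocks = {
        "environment": env.loc[ids],
        "broad_dbmem": broad.scores.loc[ids],
    }
    rows = []
    for name, block in [
        ("all", pd.concat(resp_blocks.values(), axis=1)),
        *resp_blocks.items(),
    ]:
        Y = block.to_numpy(dtype=float)
        data = pd.DataFrame(
            Y, columns=[f"y{j}" for j in range(Y.shape[1])], index=ids
        )
        data["module"] = labels.to_numpy()
        formula = " + ".join(data.columns[:-1]) + " ~ C(module)"
        try:
            mv = MANOVA.from_formula(formula, data=data)
            table = mv.mv_test().results["C(module)"]["stat"]
        except Exception as err:  # singular within-group covariance, etc.
            raise ValueError(
                f"MANOVA failed for response block {name!r} ({err}); "
                "drop collinear response columns and retry"
            ) from None
        wilks = table.loc["Wilks' lambda"]
        rows.append(
            {
                "responses": name,
                "wilks_lambda": float(wilks["Value"]),
                "F": float(wilks["F Value"]),
                "df_num": float(wilks["Num DF"]),
                "df_den": float(wilks["Den DF"]),
                "p": float(wilks["Pr > F"]),
            }
        )
    return pd.DataFrame(rows)


def moran_i(
    values: pd.Series, G: GeodesicMatrix, threshold_km: float, *, n_perm: int = 199, seed: int = 0
) -> dict:
    """Moran's I of a site variable under a distance-band spatial weight.

    Weights are 1 for pairs within ``threshold_km`` (row-standardized); the
    p-value is a two-sided permutation test.  Used to report whether depth is
    spatially autocorrelated before it is offered as an environmental
    predictor; nothing is dropped automatically.
    """
    x = values.loc[list(G.ids)].to_numpy(dtype=float)
    n = len(x)
    W = ((G.values <= threshold_km) & ~np.eye(n, dtype=bool)).astype(float)
    rows = W.sum(axis=1)
    if (rows == 0).any():
        raise ValueError("threshold leaves isolated sites in the weight matrix")
    W /= rows[:, None]

    def stat(v: np.ndarray) -> float:
        vc = v - v.mean()
        return float(n / W.sum() * (vc @ W @ vc) / (vc @ vc))

    i_obs = stat(x)
    rng = np.random.default_rng(seed)
    exceed = sum(
        1
        for _ in range(n_perm)
        if abs(stat(rng.permutation(x)) - (-1.0 / (n - 1)))
        >= abs(i_obs - (-1.0 / (n - 1))) - 1e-12
    )
    return {"moran_i": i_obs, "p": (1 + exceed) / (1 + n_perm), "expected": -1.0 / (n - 1)}
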
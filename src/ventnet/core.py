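"""Domain types and I/O for vent-site assemblage data.

The central object is the :class:`PresenceMatrix`, a binary site-by-species
occurrence table.  Occurrence data from remote habitats such as hydrothermal
vents are presence-only: a 0 means "not recorded", never "confirmed absent",
and no imputation is ever performed on it.  Everything downstream — the
Sørensen similarity network, SIMPROF clustering, the bipartite site–species
graph — is derived from this one table plus a per-site metadata table
(coordinates, depth, tectonic setting, region).

CSV is the canonical interchange format.  Site and species order is preserved
exactly as loaded, and all outputs are reported against identifiers rather
than positions.
"""

from __future__ import annotations

import json
import numbers
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "PresenceMatrix",
    "DEFAULT_TECTONIC_VOCABULARY",
    "read_presence_matrix",
    "write_presence_matrix",
    "read_site_metadata",
    "validate_site_metadata",
    "species_richness",
    "assemble_site_report",
    "write_outputs",
    "load_vent_site_table",
    "load_published_site_results",
]

#: Closed vocabulary for the tectonic-setting covariate.  Extensible by
#: passing an enlarged iterable to :func:`read_site_metadata`.
DEFAULT_TECTONIC_VOCABULARY = frozenset(
    {"arc volcano", "back-arc spreading center"}
)

METADATA_COLUMNS = (
    "site_id",
    "name",
    "latitude",
    "longitude",
    "depth_m",
    "tectonic_setting",
    "region",
)

REPORT_COLUMNS = (
    "site_id",
    "name",
    "module",
    "z",
    "participation",
    "role",
    "betweenness",
    "species_richness",
    "simprof_group",
)


@dataclass(frozen=True)
class PresenceMatrix:
    """Binary site-by-species occurrence table.

    Parameters
    ----------
    site_ids, species_ids :
        Unique ordered identifiers; order is preserved from the source file.
    values :
        ``(n_sites, n_species)`` array of 0/1 indicators.  Every site must
        record at least one species and every species at least one site.
    """

    site_ids: tuple[str, ...]
    species_ids: tuple[str, ...]
    values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        vals = np.asarray(self.values)
        if vals.ndim != 2 or vals.shape != (len(self.site_ids), len(self.species_ids)):
            raise ValueError(
                f"values shape {vals.shape} does not match "
                f"{len(self.site_ids)} sites x {len(self.species_ids)} species"
            )
        if not np.isin(vals, (0, 1)).all():
            bad = np.argwhere(~np.isin(vals, (0, 1)))[0]
            raise ValueError(
                f"non-binary cell at site {self.site_ids[bad[0]]!r}, "
                f"species {self.species_ids[bad[1]]!r}"
            )
        object.__setattr__(self, "values", vals.astype(np.int8))
        for label, ids in (("site", self.site_ids), ("species", self.species_ids)):
            if len(set(ids)) != len(ids):
                dupes = sorted({x for x in ids if list(ids).count(x) > 1})
                raise ValueError(f"duplicate {label} ids: {dupes}")
        empty_rows = [s for s, r in zip(self.site_ids, vals.sum(axis=1)) if r == 0]
        if empty_rows:
            raise ValueError(f"sites with no recorded species: {empty_rows}")
        empty_cols = [s for s, c in zip(self.species_ids, vals.sum(axis=0)) if c == 0]
        if empty_cols:
            raise ValueError(f"species with no recorded site: {empty_cols}")

    @property
    def n_sites(self) -> int:
        return len(self.site_ids)

    @property
    def n_species(self) -> int:
        return len(self.species_ids)

    @property
    def n_occurrences(self) -> int:
        """Total number of 1-cells (edge count of the bipartite graph)."""
        return int(self.values.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values.copy(),
            index=pd.Index(self.site_ids, name="site_id"),
            columns=list(self.species_ids),
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "PresenceMatrix":
        return cls(
            site_ids=tuple(str(i) for i in frame.index),
            species_ids=tuple(str(c) for c in frame.columns),
            values=frame.to_numpy(),
        )

    def restrict_sites(self, sites: Sequence[str]) -> "PresenceMatrix":
        """Sub-matrix for the given sites, dropping species left unrecorded."""
        idx = [self.site_ids.index(s) for s in sites]
        sub = self.values[idx]
        keep = sub.sum(axis=0) > 0
        return PresenceMatrix(
            site_ids=tuple(sites),
            species_ids=tuple(np.asarray(self.species_ids)[keep]),
            values=sub[:, keep],
        )


def read_presence_matrix(path: str | Path, *, blank_is_zero: bool = False) -> PresenceMatrix:
    """Load a site-by-species CSV (first column site id, header species ids).

    Cells must parse as 0 or 1; with ``blank_is_zero`` empty cells are read as
    absences.  Duplicate identifiers, non-binary cells and empty rows or
    columns are rejected with the offending coordinate named.
    """
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
    species = [h.strip() for h in _split_csv_header(header)[1:]]
    if len(set(species)) != len(species):
        dupes = sorted({s for s in species if species.count(s) > 1})
        raise ValueError(f"duplicate species ids in {path.name}: {dupes}")
    frame = pd.read_csv(path, index_col=0)
    if frame.index.duplicated().any():
        dupes = sorted(frame.index[frame.index.duplicated()].unique())
        raise ValueError(f"duplicate site ids in {path.name}: {dupes}")
    if blank_is_zero:
        frame = frame.fillna(0)
    if frame.isna().any().any():
        site, sp = next(
            (i, c) for i in frame.index for c in frame.columns if pd.isna(frame.at[i, c])
        )
        raise ValueError(
            f"missing cell at site {site!r}, species {sp!r} "
            "(pass blank_is_zero=True to read blanks as absences)"
        )
    frame.columns = species
    return PresenceMatrix.from_frame(frame)


def _split_csv_header(line: str) -> list[str]:
    # A one-line CSV parse that honours quoted commas.
    import csv
    import io

    return next(csv.reader(io.StringIO(line)))


def write_presence_matrix(matrix: PresenceMatrix, path: str | Path) -> None:
    matrix.to_frame().to_csv(path)


def species_richness(matrix: PresenceMatrix) -> pd.Series:
    """Number of recorded species per site (row sums of the matrix)."""
    return pd.Series(
        matrix.values.sum(axis=1), index=list(matrix.site_ids), name="species_richness"
    )


def validate_site_metadata(
    meta: pd.DataFrame,
    matrix: PresenceMatrix | None = None,
    *,
    tectonic_vocabulary: Iterable[str] = DEFAULT_TECTONIC_VOCABULARY,
) -> pd.DataFrame:
    """Validate a site-metadata table and return it indexed by ``site_id``.

    Checks coordinate and depth ranges, the tectonic-setting vocabulary, id
    uniqueness, and (when a matrix is given) that every matrix site has
    exactly one metadata row.
    """
    meta = meta.copy()
    if meta.index.name == "site_id":
        meta = meta.reset_index(drop="site_id" in meta.columns)
    missing_cols = [c for c in METADATA_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise ValueError(f"metadata missing columns: {missing_cols}")
    if meta["site_id"].duplicated().any():
        dupes = sorted(meta.loc[meta["site_id"].duplicated(), "site_id"])
        raise ValueError(f"duplicate site ids in metadata: {dupes}")
    for col, lo, hi in (("latitude", -90.0, 90.0), ("longitude", -180.0, 180.0)):
        vals = pd.to_numeric(meta[col], errors="raise")
        bad = meta.loc[(vals < lo) | (vals > hi), "site_id"]
        if len(bad):
            raise ValueError(f"{col} out of [{lo}, {hi}] for sites: {sorted(bad)}")
        meta[col] = vals.astype(float)
    depth = pd.to_numeric(meta["depth_m"], errors="raise")
    bad = meta.loc[~(depth > 0), "site_id"]
    if len(bad):
        raise ValueError(f"non-positive depth for sites: {sorted(bad)}")
    meta["depth_m"] = depth.astype(float)
    vocab = set(tectonic_vocabulary)
    unknown = sorted(set(meta["tectonic_setting"]) - vocab)
    if unknown:
        raise ValueError(
            f"tectonic settings {unknown} not in vocabulary {sorted(vocab)}"
        )
    meta = meta.set_index("site_id", drop=False)
    if matrix is not None:
        absent = [s for s in matrix.site_ids if s not in meta.index]
        if absent:
            raise ValueError(f"matrix sites missing from metadata: {absent}")
        meta = meta.loc[list(matrix.site_ids)]
    return meta


def read_site_metadata(
    path: str | Path,
    matrix: PresenceMatrix | None = None,
    *,
    tectonic_vocabulary: Iterable[str] = DEFAULT_TECTONIC_VOCABULARY,
) -> pd.DataFrame:
    """Read and validate the site-metadata CSV (see :data:`METADATA_COLUMNS`)."""
    return validate_site_metadata(
        pd.read_csv(path), matrix, tectonic_vocabulary=tectonic_vocabulary
    )


def load_vent_site_table() -> pd.DataFrame:
    """The published Northwest Pacific vent-site metadata table (36 sites)."""
    with resources.files("ventnet.data").joinpath("northwest_pacific_sites.csv").open() as fh:
        return validate_site_metadata(pd.read_csv(fh))


def load_published_site_results() -> pd.DataFrame:
    """Published per-site network statistics, for qualitative comparison only."""
    with resources.files("ventnet.data").joinpath("published_site_results.csv").open() as fh:
        return pd.read_csv(fh, index_col="site_id")


def assemble_site_report(
    matrix: PresenceMatrix,
    meta: pd.DataFrame | None = None,
    *,
    modules: Mapping[str, object] | None = None,
    z: Mapping[str, float] | None = None,
    participation: Mapping[str, float] | None = None,
    roles: Mapping[str, str] | None = None,
    betweenness: Mapping[str, float] | None = None,
    simprof_groups: Mapping[str, object] | None = None,
) -> pd.DataFrame:
    """Combine per-site results into a single report table (one row per site).

    Any stage not yet computed may be omitted; its column is filled with NA.
    """
    sites = list(matrix.site_ids)
    report = pd.DataFrame(index=pd.Index(sites, name="site_id"))
    report["site_id"] = sites
    if meta is not None:
        report["name"] = [meta.at[s, "name"] if s in meta.index else pd.NA for s in sites]
    else:
        report["name"] = pd.NA
    for col, mapping in (
        ("module", modules),
        ("z", z),
        ("participation", participation),
        ("role", roles),
        ("betweenness", betweenness),
        ("simprof_group", simprof_groups),
    ):
        report[col] = (
            [mapping.get(s, pd.NA) for s in sites] if mapping is not None else pd.NA
        )
    report["species_richness"] = species_richness(matrix).to_numpy()
    return report[list(REPORT_COLUMNS)]


def write_outputs(
    destination: str | Path,
    *,
    report: pd.DataFrame | None = None,
    similarity_network: "object | None" = None,
    bipartite_graph: nx.Graph | None = None,
    module_summary: pd.DataFrame | None = None,
    module_sharing: pd.DataFrame | None = None,
    manifest: Mapping[str, object] | None = None,
) -> list[Path]:
    """Write whichever pipeline outputs are available to ``destination``.

    Emits the site report and module summaries as CSV, the two networks as
    GraphML (edge attribute ``similarity``/``dissimilarity``; node attributes
    as carried by the graphs), and an optional JSON run manifest.  At least
    one artefact must be supplied; an all-``None`` call raises and names the
    missing stages so partially-run pipelines fail loudly rather than writing
    an empty directory.
    """
    supplied = {
        "report": report,
        "similarity_network": similarity_network,
        "bipartite_graph": bipartite_graph,
        "module_summary": module_summary,
        "module_sharing": module_sharing,
        "manifest": manifest,
    }
    if all(v is None for v in supplied.values()):
        raise ValueError(
            "nothing to write; missing stages: " + ", ".join(supplied)
        )
    destination = Path(destination)
    destination.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def _emit(name: str, writer) -> None:
        target = destination / name
        writer(target)
        written.append(target)

    if report is not None:
        _emit("site_report.csv", lambda p: report.to_csv(p, index=False))
    if similarity_network is not None:
        graph = getattr(similarity_network, "graph", similarity_network)
        _emit("similarity_network.graphml", lambda p: nx.write_graphml(graph, p))
    if bipartite_graph is not None:
        _emit("bipartite_network.graphml", lambda p: nx.write_graphml(bipartite_graph, p))
    if module_summary is not None:
        _emit("module_summary.csv", lambda p: module_summary.to_csv(p, index=False))
    if module_sharing is not None:
        _emit("module_sharing.csv", lambda p: module_sharing.to_csv(p, index=False))
    if manifest is not None:
        _emit(
            "run_manifest.json",
            lambda p: p.write_text(json.dumps(_jsonable(manifest), indent=2) + "\n"),
        )
    return written


def _jsonable(obj):
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, numbers.Integral):
        return int(obj)
    if isinstance(obj, numbers.Real):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj
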
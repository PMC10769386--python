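"""Readers/writers for cell tables, region annotations, clinical tables and
gene-expression cohorts, plus the shared pipeline configuration.

The pipeline starts from per-cell tables exported by image-analysis software
(one row per segmented cell: id, sample, x/y centroid in micrometers, and one
mean-intensity column per marker). Coordinates are Cartesian micrometers with
an arbitrary per-sample origin; all distances downstream are Euclidean in this
frame. The delimited dialect is fixed (comma separator, ``.`` decimal, UTF-8,
header required) so round-trips are bit-exact.

Missing intensities are rejected rather than imputed: gating on an imputed
intensity would be silently wrong.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import shape as _geojson_shape

__all__ = [
    "DEFAULT_MARKERS",
    "DEFAULT_RING_EDGES",
    "REGION_LABELS",
    "CellTableError",
    "AnnotationError",
    "CohortError",
    "PipelineConfig",
    "CellRecord",
    "ClinicalRecord",
    "RegionAnnotation",
    "read_cell_table",
    "write_cell_table",
    "read_clinical_table",
    "write_clinical_table",
    "read_region_annotations",
    "annotation_labels",
    "read_expression_cohort",
    "write_table_with_sidecar",
]

#: Marker panel of the multiplex assay (tumor marker CK-SOX10 written CKSOX10).
DEFAULT_MARKERS = (
    "NOS2",
    "COX2",
    "CD8",
    "CD3",
    "PD1",
    "CKSOX10",
    "IFNG",
    "EPCAM",
    "CD44V6",
)

#: Concentric census ring edges in micrometers: 0-25, 25-50, 50-100, 100-150,
#: 150-200.
DEFAULT_RING_EDGES = (0.0, 25.0, 50.0, 100.0, 150.0, 200.0)

REGION_LABELS = (
    "lymphoid_aggregate",
    "fragment",
    "nest_edge_NOS2pos",
    "nest_edge_NOS2neg",
    "core",
    "stroma",
    "unassigned",
)

REQUIRED_CELL_COLUMNS = ("cell_id", "sample_id", "x_um", "y_um")


class CellTableError(ValueError):
    """Malformed cell table (missing column, bad value, duplicate id)."""


class AnnotationError(ValueError):
    """Malformed GeoJSON region annotation."""


class CohortError(ValueError):
    """Malformed expression/clinical cohort input."""


@dataclass(frozen=True)
class CellRecord:
    """One segmented cell: coordinates (um) plus per-marker intensities."""

    cell_id: str
    sample_id: str
    x: float
    y: float
    intensity: dict[str, float]
    region_label: str = "unassigned"


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-sample outcome: 5-year group label, survival time, event flag."""

    sample_id: str
    group: str  # "Deceased" | "Alive"
    time_months: float
    event: bool


@dataclass(frozen=True)
class RegionAnnotation:
    polygon: shapely.Polygon
    region: str


@dataclass
class PipelineConfig:
    """Shared configuration; every stage records it (plus the seed) in output
    sidecars so runs are auditable."""

    markers: tuple[str, ...] = DEFAULT_MARKERS
    ring_edges: tuple[float, ...] = DEFAULT_RING_EDGES
    # embedding
    n_neighbors: int = 15
    min_dist: float = 0.1
    subsample_n: int = 50_000
    # clustering
    k_min: int = 2
    k_max: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        edges = tuple(float(e) for e in self.ring_edges)
        if len(edges) < 2 or edges[0] != 0.0:
            raise ValueError("ring_edges must start at 0 and have >= 2 entries")
        if any(b <= a for a, b in zip(edges, edges[1:])):
            raise ValueError("ring_edges must be strictly increasing")
        self.ring_edges = edges

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def read_cell_table(path: str | Path, config: PipelineConfig | None = None) -> pd.DataFrame:
    """Read a per-cell CSV into a validated DataFrame.

    Required columns: ``cell_id``, ``sample_id``, ``x_um``, ``y_um`` and one
    column per configured marker. Unknown columns are preserved as
    passthrough metadata. Raises :class:`CellTableError` with the offending
    column name or row index on contract violations.
    """
    config = config or PipelineConfig()
    df = pd.read_csv(path, dtype={"cell_id": str, "sample_id": str})
    return validate_cell_table(df, config)


def validate_cell_table(df: pd.DataFrame, config: PipelineConfig | None = None) -> pd.DataFrame:
    config = config or PipelineConfig()
    for col in REQUIRED_CELL_COLUMNS:
        if col not in df.columns:
            raise CellTableError(f"missing required column {col!r}")
    for marker in config.markers:
        if marker not in df.columns:
            raise CellTableError(f"missing required marker column {marker!r}")
    df = df.copy()
    df["cell_id"] = df["cell_id"].astype(str)
    df["sample_id"] = df["sample_id"].astype(str)

    coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
    bad = ~np.isfinite(coords).all(axis=1)
    if bad.any():
        raise CellTableError(f"non-finite coordinate at row {int(np.flatnonzero(bad)[0])}")
    if (coords < 0).any():
        row = int(np.flatnonzero((coords < 0).any(axis=1))[0])
        raise CellTableError(f"negative coordinate at row {row}")

    inten = df[list(config.markers)].to_numpy(dtype=float)
    bad = ~np.isfinite(inten)
    if bad.any():
        row = int(np.flatnonzero(bad.any(axis=1))[0])
        raise CellTableError(f"missing or non-finite intensity at row {row}")
    if (inten < 0).any():
        row = int(np.flatnonzero((inten < 0).any(axis=1))[0])
        raise CellTableError(f"negative intensity at row {row}")

    dup = df.duplicated(subset=["sample_id", "cell_id"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise CellTableError(f"duplicate (sample_id, cell_id) at row {row}")
    return df


def write_cell_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_clinical_table(path: str | Path) -> pd.DataFrame:
    """Read the per-sample clinical CSV (sample_id, group, time_months, event)."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    return validate_clinical_table(df)


def validate_clinical_table(df: pd.DataFrame) -> pd.DataFrame:
    for col in ("sample_id", "group", "time_months", "event"):
        if col not in df.columns:
            raise CohortError(f"missing required clinical column {col!r}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    bad_group = ~df["group"].isin(["Deceased", "Alive"])
    if bad_group.any():
        raise CohortError(
            f"unknown group label {df.loc[bad_group, 'group'].iloc[0]!r} "
            "(expected Deceased or Alive)"
        )
    if (df["time_months"].to_numpy(dtype=float) <= 0).any():
        raise CohortError("survival time_months must be > 0")
    if df["sample_id"].duplicated().any():
        raise CohortError("one clinical record per sample required")
    df["event"] = df["event"].astype(bool)
    return df


def write_clinical_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def read_region_annotations(path: str | Path) -> list[RegionAnnotation]:
    """Read pathologist region annotations from a GeoJSON FeatureCollection.

    Each feature must be a polygon in the same micrometer frame as the cells
    and carry a ``region`` property. Invalid (e.g. self-intersecting)
    geometries are fatal, reported with the feature index.
    """
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise AnnotationError("expected a GeoJSON FeatureCollection")
    out: list[RegionAnnotation] = []
    for i, feature in enumerate(doc.get("features", [])):
        props = feature.get("properties") or {}
        if "region" not in props:
            raise AnnotationError(f"feature {i} lacks a 'region' property")
        geom = _geojson_shape(feature["geometry"])
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise AnnotationError(f"feature {i} is not a polygon ({geom.geom_type})")
        if not geom.is_valid:
            raise AnnotationError(f"feature {i} has invalid geometry (self-intersection?)")
        out.append(RegionAnnotation(polygon=geom, region=str(props["region"])))
    return out


def annotation_labels(
    cells: pd.DataFrame, annotations: list[RegionAnnotation]
) -> pd.Series:
    """Point-in-polygon region label per cell; 'unassigned' outside all
    polygons. Later annotations take precedence on overlap."""
    labels = np.array(["unassigned"] * len(cells), dtype=object)
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    for ann in annotations:
        inside = shapely.contains_xy(ann.polygon, x, y) | shapely.intersects_xy(
            ann.polygon, x, y
        )
        labels[inside] = ann.region
    return pd.Series(labels, index=cells.index, name="region_label")


def _read_series_matrix(path: str | Path) -> pd.DataFrame:
    """Parse the GEO series-matrix text dialect: metadata lines start with
    '!', the expression table sits between !series_matrix_table_begin/end."""
    rows: list[str] = []
    in_table = False
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                break
            if in_table:
                rows.append(line)
    if not rows:
        raise CohortError("no series_matrix table found")
    from io import StringIO

    df = pd.read_csv(StringIO("".join(rows)), sep="\t")
    df = df.set_index(df.columns[0])
    df.index = df.index.astype(str).str.strip('"')
    df.columns = [str(c).strip('"') for c in df.columns]
    return df


def read_expression_cohort(
    path_expr: str | Path,
    path_clinical: str | Path,
    er_status_column: str | None = None,
    er_negative_value: str = "negative",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a genes x samples expression matrix plus its clinical table.

    Accepts either the GEO series-matrix dialect or a plain delimited matrix
    whose first column holds gene symbols. Only samples present in both
    tables are returned; if ``er_status_column`` is given, the cohort is
    restricted to ER-negative samples first.
    """
    path_expr = Path(path_expr)
    with open(path_expr, encoding="utf-8") as fh:
        head = fh.readline()
    if head.startswith("!") or head.startswith("^"):
        expr = _read_series_matrix(path_expr)
    else:
        sep = "\t" if "\t" in head else ","
        expr = pd.read_csv(path_expr, sep=sep, index_col=0)
        expr.index = expr.index.astype(str)
    clinical = read_clinical_table_loose(path_clinical)

    if er_status_column is not None:
        if er_status_column not in clinical.columns:
            raise CohortError(f"ER status column {er_status_column!r} not in clinical table")
        keep = (
            clinical[er_status_column].astype(str).str.lower()
            == er_negative_value.lower()
        )
        clinical = clinical.loc[keep]

    shared = [s for s in expr.columns if s in set(clinical["sample_id"])]
    expr = expr[shared]
    clinical = clinical.set_index("sample_id").loc[shared].reset_index()
    return expr, clinical


def read_clinical_table_loose(path: str | Path) -> pd.DataFrame:
    """Clinical reader for expression cohorts: requires sample_id,
    time_months, event; extra columns (e.g. ER status) pass through."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "time_months", "event"):
        if col not in df.columns:
            raise CohortError(f"missing required clinical column {col!r}")
    df = df.copy()
    df["sample_id"] = df["sample_id"].astype(str)
    df["event"] = df["event"].astype(bool)
    return df


def gene_row(expr: pd.DataFrame, gene: str) -> pd.Series:
    """Look up one gene's expression across samples; fatal with candidate
    symbols when absent."""
    if gene not in expr.index:
        cands = [g for g in expr.index.astype(str) if gene.lower() in g.lower()][:10]
        raise CohortError(f"gene {gene!r} not found; candidates: {cands or sorted(expr.index)[:10]}")
    return expr.loc[gene]


def write_table_with_sidecar(
    df: pd.DataFrame,
    path: str | Path,
    config: PipelineConfig,
    seed: int,
    extra: dict | None = None,
) -> None:
    """Write a derived CSV plus a JSON sidecar recording config + seed."""
    path = Path(path)
    df.to_csv(path, index=False)
    from spatialtme import __version__

    meta = {
        "config": config.to_dict(),
        "seed": int(seed),
        "version": __version__,
    }
    if extra:
        meta.update(extra)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=2))


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()
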
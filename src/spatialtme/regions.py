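"""Tissue-region derivation from gated cells.

The five basic regions are derived from a rasterized tumor mask: grid
occupancy of tumor-marker-positive cells (default CK-SOX10), morphologically
closed, split into connected components. Components below 0.05 mm^2 are
*fragments* (tumor satellitosis); components at or above 0.05 mm^2 are
*nests*, whose cells are split into an *edge* band (within 50 um of the
component boundary, flagged NOS2+ when at least 5% of edge cells are NOS2
positive) and a *core*. Outside the mask, single-linkage clusters of at
least 20 CD3+ cells at 30 um linkage are *lymphoid aggregates*; all
remaining cells are *stroma*. Cores whose CD8+ density falls below
100 cells/mm^2 carry an immune-desert flag.

Grid spacing (6.25 um) and the closing radius (50 um, matching the
inter-cell spacing scale of realistic cell densities) bound the geometric
resolution; component boundaries are extracted from a Gaussian-smoothed
mask contoured slightly below 0.5, offsetting the inward bias of a mask
built from point-sampled cell occupancy. When pathologist GeoJSON
annotations are available they override derived labels
(see :func:`spatialtme.io_model.annotation_labels`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree
from skimage import measure

__all__ = [
    "RegionConfig",
    "RegionLabeling",
    "derive_regions",
    "region_composition",
    "boundary_gap_distance",
]


@dataclass
class RegionConfig:
    tumor_marker: str = "CKSOX10"
    grid_spacing: float = 6.25  # um
    closing_radius: float = 50.0  # um
    boundary_smoothing: float = 18.75  # um; Gaussian smoothing of the mask
    boundary_level: float = 0.35  # contour level; <0.5 offsets the inward
    # bias of a mask built from point-sampled cell occupancy
    fragment_max_area: float = 0.05  # mm^2 (single area cut: fragment below)
    nest_min_area: float = 0.05  # mm^2 (nest at/above)
    edge_band_width: float = 50.0  # um
    nos2_edge_fraction: float = 0.05
    lymphoid_min_cells: int = 20
    lymphoid_link_distance: float = 30.0  # um
    immune_desert_density: float = 100.0  # CD8+ cells/mm^2

    def __post_init__(self) -> None:
        if self.fragment_max_area <= 0 or self.nest_min_area <= 0:
            raise ValueError("areas must be > 0")
        if self.edge_band_width <= 0:
            raise ValueError("edge band width must be > 0")


@dataclass
class RegionLabeling:
    """Per-cell region labels plus per-instance attributes for one sample."""

    labels: np.ndarray  # (n_cells,) object: region label per cell
    instance_id: np.ndarray  # (n_cells,) int: component/aggregate id, 0 = none
    instances: pd.DataFrame  # instance, kind, area_mm2, core_area_mm2, ...
    boundary_points: dict = field(default_factory=dict)  # nest id -> (m, 2) um
    config: RegionConfig = field(default_factory=RegionConfig)


def _disk(radius_cells: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius_cells : radius_cells + 1, -radius_cells : radius_cells + 1]
    return (xx**2 + yy**2) <= radius_cells**2


def _union_find_clusters(xy: np.ndarray, link: float) -> np.ndarray:
    """Single-linkage clusters at a fixed link distance (union-find over
    k-d-tree pairs). Returns a cluster index per point."""
    n = len(xy)
    parent = np.arange(n)

    def find(a: int) -> int:
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    tree = cKDTree(xy)
    for i, j in tree.query_pairs(link):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
    roots = np.array([find(i) for i in range(n)])
    _, labels = np.unique(roots, return_inverse=True)
    return labels


def derive_regions(
    cells: pd.DataFrame,
    tumor_pos: np.ndarray,
    cd3_pos: np.ndarray,
    nos2_pos: np.ndarray,
    cd8_pos: np.ndarray | None = None,
    config: RegionConfig | None = None,
) -> RegionLabeling:
    """Derive region labels for the cells of one sample.

    ``tumor_pos``/``cd3_pos``/``nos2_pos`` are per-cell positivity masks
    (tumor-marker gating happens upstream). ``cd8_pos`` enables the
    immune-desert flag on nest cores.
    """
    config = config or RegionConfig()
    n = len(cells)
    tumor_pos = np.asarray(tumor_pos, dtype=bool)
    cd3_pos = np.asarray(cd3_pos, dtype=bool)
    nos2_pos = np.asarray(nos2_pos, dtype=bool)
    labels = np.array(["stroma"] * n, dtype=object)
    inst = np.zeros(n, dtype=int)
    instances: list[dict] = []
    boundary_points: dict[int, np.ndarray] = {}

    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)

    if not tumor_pos.any():
        warnings.warn("no tumor-marker positive cells; labeling all stroma", stacklevel=2)
    else:
        h = config.grid_spacing
        pad = config.closing_radius + 2 * h
        x0, y0 = x.min() - pad, y.min() - pad
        nxg = int(np.ceil((x.max() + pad - x0) / h)) + 1
        nyg = int(np.ceil((y.max() + pad - y0) / h)) + 1
        ix = np.clip(((x - x0) / h).astype(int), 0, nxg - 1)
        iy = np.clip(((y - y0) / h).astype(int), 0, nyg - 1)
        occ = np.zeros((nyg, nxg), dtype=bool)
        occ[iy[tumor_pos], ix[tumor_pos]] = True
        rad = max(1, int(round(config.closing_radius / h)))
        mask = ndimage.binary_closing(occ, structure=_disk(rad))
        mask |= occ  # closing never removes occupied nodes
        # cell occupancy is sparse at realistic densities; interior gaps are
        # not tissue boundaries
        mask = ndimage.binary_fill_holes(mask)

        comp, n_comp = ndimage.label(mask)
        cell_comp = comp[iy, ix]
        for c in range(1, n_comp + 1):
            comp_mask = comp == c
            area = float(comp_mask.sum()) * h * h / 1e6
            members = np.flatnonzero(cell_comp == c)
            kind = "fragment" if area < config.nest_min_area else "nest"
            rec = {
                "instance": c,
                "kind": kind,
                "area_mm2": area,
                "n_cells": int(members.size),
                "core_area_mm2": np.nan,
                "nos2_edge": False,
                "cd8_core_density": np.nan,
                "immune_desert": False,
            }
            inst[members] = c
            if kind == "fragment":
                labels[members] = "fragment"
            else:
                smooth = ndimage.gaussian_filter(
                    comp_mask.astype(float), config.boundary_smoothing / h
                )
                contours = measure.find_contours(smooth, config.boundary_level)
                bpts = (
                    np.vstack(contours)[:, ::-1] * h + np.array([x0, y0])
                    if contours
                    else np.empty((0, 2))
                )
                boundary_points[c] = bpts
                if members.size and len(bpts):
                    btree = cKDTree(bpts)
                    d_edge, _ = btree.query(np.column_stack([x[members], y[members]]))
                    is_edge = d_edge <= config.edge_band_width
                else:
                    is_edge = np.ones(members.size, dtype=bool)
                edge_members = members[is_edge]
                core_members = members[~is_edge]
                nos2_edge = (
                    nos2_pos[edge_members].mean() >= config.nos2_edge_fraction
                    if edge_members.size
                    else False
                )
                rec["nos2_edge"] = bool(nos2_edge)
                labels[edge_members] = (
                    "nest_edge_NOS2pos" if nos2_edge else "nest_edge_NOS2neg"
                )
                labels[core_members] = "core"
                # core area from the interior of the mask (distance to
                # background beyond the edge band)
                dist = ndimage.distance_transform_edt(comp_mask) * h
                core_area = float((dist > config.edge_band_width).sum()) * h * h / 1e6
                rec["core_area_mm2"] = core_area
                if cd8_pos is not None and core_area > 0:
                    dens = float(np.asarray(cd8_pos, dtype=bool)[core_members].sum()) / core_area
                    rec["cd8_core_density"] = dens
                    rec["immune_desert"] = dens < config.immune_desert_density
            instances.append(rec)

    # lymphoid aggregates: CD3+ cells outside any tumor component
    outside_cd3 = np.flatnonzero(cd3_pos & (inst == 0))
    next_id = (max((r["instance"] for r in instances), default=0)) + 1
    if outside_cd3.size:
        cl = _union_find_clusters(
            np.column_stack([x[outside_cd3], y[outside_cd3]]),
            config.lymphoid_link_distance,
        )
        for k in range(cl.max() + 1):
            members = outside_cd3[cl == k]
            if members.size >= config.lymphoid_min_cells:
                labels[members] = "lymphoid_aggregate"
                inst[members] = next_id
                instances.append(
                    {
                        "instance": next_id,
                        "kind": "lymphoid_aggregate",
                        "area_mm2": np.nan,
                        "n_cells": int(members.size),
                        "core_area_mm2": np.nan,
                        "nos2_edge": False,
                        "cd8_core_density": np.nan,
                        "immune_desert": False,
                    }
                )
                next_id += 1

    inst_df = pd.DataFrame(
        instances,
        columns=[
            "instance",
            "kind",
            "area_mm2",
            "n_cells",
            "core_area_mm2",
            "nos2_edge",
            "cd8_core_density",
            "immune_desert",
        ],
    )
    return RegionLabeling(
        labels=labels,
        instance_id=inst,
        instances=inst_df,
        boundary_points=boundary_points,
        config=config,
    )


def region_composition(
    called: pd.DataFrame,
    labeling: RegionLabeling,
    teff: np.ndarray | None = None,
) -> pd.DataFrame:
    """Percentage of each phenotype (and %CD3+CD8+ when available) per
    region. Phenotype percentages sum to 100 within each region."""
    df = pd.DataFrame(
        {
            "region": labeling.labels,
            "phenotype": called["phenotype"].astype(str).to_numpy(),
        }
    )
    tab = pd.crosstab(df["region"], df["phenotype"])
    comp = 100.0 * tab.div(tab.sum(axis=1), axis=0)
    comp["n_cells"] = tab.sum(axis=1)
    if "cd8_pos" in called.columns and "CD3" in called.columns:
        cd3cd8 = (
            called["cd8_pos"].to_numpy(dtype=bool)
            if teff is None
            else np.asarray(teff, dtype=bool)
        )
        comp["pct_CD3CD8"] = [
            100.0 * cd3cd8[labeling.labels == r].mean() if (labeling.labels == r).any() else np.nan
            for r in comp.index
        ]
    return comp


def boundary_gap_distance(
    cells: pd.DataFrame, labeling: RegionLabeling
) -> pd.DataFrame:
    """Per lymphoid aggregate: Euclidean distance from its centroid and from
    its nearest member cell to the nearest tumor-component boundary (over
    all nests; fragments have no stored boundary)."""
    all_bpts = (
        np.vstack(list(labeling.boundary_points.values()))
        if labeling.boundary_points
        else np.empty((0, 2))
    )
    if len(all_bpts) == 0:
        return pd.DataFrame(
            columns=["instance", "centroid_distance", "nearest_distance", "n_cells"]
        )
    btree = cKDTree(all_bpts)
    x = cells["x_um"].to_numpy(dtype=float)
    y = cells["y_um"].to_numpy(dtype=float)
    rows = []
    agg_ids = labeling.instances.loc[
        labeling.instances["kind"] == "lymphoid_aggregate", "instance"
    ]
    for a in agg_ids:
        members = np.flatnonzero(labeling.instance_id == a)
        pts = np.column_stack([x[members], y[members]])
        centroid = pts.mean(axis=0)
        d_cent, _ = btree.query(centroid)
        d_near = float(btree.query(pts)[0].min())
        rows.append(
            {
                "instance": int(a),
                "centroid_distance": float(d_cent),
                "nearest_distance": d_near,
                "n_cells": int(members.size),
            }
        )
    return pd.DataFrame(rows, columns=["instance", "centroid_distance", "nearest_distance", "n_cells"])
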
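"""Synthetic-tissue and synthetic-cohort generators with ground truth.

The generator plants the three immune architectures the analysis is built to
detect, on a canvas of spatially clustered tumor nests:

* ``fully_inflamed`` — CD8+ T cells in dense pockets scattered through nests
  and stroma alike (deep core infiltration), with only background NOS2/COX2.
* ``stroma_restricted`` — CD8+ pockets confined to the stroma 50-100 um
  outside nest boundaries, NOS2+ tumor cells in a 50-um edge band, COX2+
  cells scattered through nests, EpCAM enriched at NOS2+ edges.
* ``immune_desert`` — COX2+ foci inside nest cores with CD44v6, and almost
  no CD8 anywhere (core CD8+ density well below 100 cells/mm^2).

Tumor nests are a parent/offspring disc process (Poisson parents, uniform
offspring inside non-overlapping discs) so true region labels — fragment,
nest edge, core, stroma, lymphoid aggregate — are available analytically.
Marker intensities are two-component log-normal mixtures: negatives
LogNormal(log 5, 0.5), positives LogNormal(log 200, ~0.1-0.15), separated
far enough that the per-sample mean + k*SD gradient gate recovers the
planted positives; planted positive fractions are a few percent of cells
(concentrated into foci/pockets/bands), matching both what the gate can
resolve on a mixture and the per-sample %Cells scale of real cohorts.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from spatialtme.gating import phenotype_label

__all__ = [
    "ARCHETYPES",
    "TissueArchetypeSpec",
    "SyntheticDataError",
    "simulate_tissue",
    "simulate_cohort",
    "simulate_expression_cohort",
]

ARCHETYPES = ("fully_inflamed", "stroma_restricted", "immune_desert", "mixed")

TRUTH_FLAGS = (
    "tumor",
    "cd8",
    "cd3",
    "nos2",
    "cox2",
    "pd1",
    "ifng",
    "epcam",
    "cd44v6",
)

_MARKER_FOR_FLAG = {
    "tumor": "CKSOX10",
    "cd8": "CD8",
    "cd3": "CD3",
    "nos2": "NOS2",
    "cox2": "COX2",
    "pd1": "PD1",
    "ifng": "IFNG",
    "epcam": "EPCAM",
    "cd44v6": "CD44V6",
}


class SyntheticDataError(ValueError):
    pass


@dataclass
class TissueArchetypeSpec:
    """Generative parameters for one synthetic sample.

    Archetype-dependent fields default to ``None`` and are resolved by
    :meth:`resolved`; all rates are per cell unless suffixed ``_per_mm2``.
    """

    archetype: str = "fully_inflamed"
    canvas: tuple[float, float] = (2800.0, 2800.0)  # um x um
    # nest (parent/disc) process -- shared across archetypes so the generic
    # nest/stroma neighborhoods are comparable between outcome groups
    nest_intensity_per_mm2: float = 1.0
    nest_radius_range: tuple[float, float] = (200.0, 300.0)
    fragment_radius_range: tuple[float, float] = (80.0, 120.0)
    fragment_fraction: float = 0.3
    min_nest_separation: float = 40.0
    # compartment densities (cells/mm^2)
    tumor_density: float = 4500.0
    stroma_density: float = 1700.0
    # a minority of nests are sparse (lower cellularity) in every archetype,
    # so low-density nest neighborhoods are not group-specific
    sparse_nest_prob: float = 0.25
    sparse_nest_density: float = 2500.0  # cells/mm^2
    # CD8 geography: two pocket populations.  Nest pockets are large dense
    # infiltration foci inside tumor nests (the fully-inflamed niche);
    # stroma pockets are smaller aggregates 50-100 um outside nest
    # boundaries (present in inflamed and stroma-restricted tissue alike,
    # so stromal T-cell aggregates per se are not outcome-specific).
    nest_pocket_radius: float = 150.0
    nest_pocket_cells: float = 1000.0
    nest_pocket_cd8_fraction: float = 0.95
    nest_pockets_per_mm2: float | None = None
    cd8_pocket_radius: float = 60.0
    cd8_cells_per_pocket: float = 80.0
    cd8_pockets_per_mm2: float | None = None
    cd8_diffuse_per_mm2: float | None = None
    cd8_core_allowed: bool | None = None  # False -> no diffuse CD8 inside nests
    pocket_cd8_fraction: float = 0.75
    pocket_cd3only_fraction: float = 0.67  # of non-CD8 pocket cells
    # NOS2 / COX2 geography.  NOS2+ tumor cells sit in short arc segments of
    # the nest edge (marginal foci); the immune-desert COX2+ territory is the
    # thinned core of one dominant nest, so it spans more than the census
    # ring range while staying a gateable few percent of the sample's cells.
    big_nest_radius_range: tuple[float, float] | None = None
    nos2_edge_band: float = 50.0
    nos2_edge_nest_prob: float | None = None  # fraction of nests with arcs
    nos2_arc_count: int = 2
    nos2_arc_halfwidth_deg: float = 30.0
    nos2_edge_rate: float | None = None
    nos2_background_rate: float = 0.002
    cox2_nest_rate: float | None = None
    cox2_edge_rate: float | None = None  # co-expression within NOS2+ arcs
    cox2_core_rate: float = 0.98
    cox2_core_density: float = 5000.0  # cellularity of the desert COX2+ nest
    cox2_focus_radius: float | None = None
    cox2_foci_per_nest: float | None = None
    cox2_max_foci: int = 3  # per-sample cap keeps COX2+ a gateable few % of cells
    cox2_focus_rate: float = 0.95
    cox2_background_rate: float = 0.002
    # auxiliary markers
    pd1_fraction_of_cd8: float | None = None
    ifng_fraction_of_cd8: float = 0.4
    epcam_edge_rate: float | None = None
    epcam_background_rate: float = 0.01
    cd44v6_focus_rate: float | None = None
    cd44v6_background_rate: float = 0.003
    # intensity model (log-normal mixture)
    negative_log_mean: float = float(np.log(5.0))
    negative_log_sd: float = 0.5
    positive_log_mean: float = float(np.log(200.0))
    positive_log_sd: dict = field(default_factory=lambda: {"CD8": 0.15})
    positive_log_sd_default: float = 0.1
    seed: int = 0

    _ARCHETYPE_DEFAULTS = {
        # backgrounds (diffuse CD8, scattered nest COX2) are near-identical
        # across archetypes so only the planted niches, not generic tissue,
        # separate the outcome groups
        "fully_inflamed": dict(
            cox2_focus_radius=70.0,
            nest_pockets_per_mm2=0.4,
            cd8_pockets_per_mm2=0.5,
            cd8_diffuse_per_mm2=4.0,
            cd8_core_allowed=True,
            nos2_edge_nest_prob=0.5,
            nos2_edge_rate=0.15,
            cox2_nest_rate=0.01,
            cox2_edge_rate=0.15,
            cox2_foci_per_nest=0.0,
            pd1_fraction_of_cd8=0.1,
            epcam_edge_rate=0.0,
            cd44v6_focus_rate=0.0,
        ),
        "stroma_restricted": dict(
            cox2_focus_radius=70.0,
            nest_pockets_per_mm2=0.0,
            cd8_pockets_per_mm2=0.8,
            cd8_diffuse_per_mm2=4.0,
            cd8_core_allowed=True,
            nos2_edge_nest_prob=1.0,
            nos2_edge_rate=0.3,
            cox2_nest_rate=0.01,
            cox2_edge_rate=0.3,
            cox2_foci_per_nest=0.0,
            pd1_fraction_of_cd8=0.4,
            epcam_edge_rate=0.3,
            cd44v6_focus_rate=0.0,
        ),
        "immune_desert": dict(
            cox2_focus_radius=70.0,
            nest_pockets_per_mm2=0.0,
            cd8_pockets_per_mm2=0.0,
            cd8_diffuse_per_mm2=4.0,
            cd8_core_allowed=True,
            big_nest_radius_range=(190.0, 220.0),
            nos2_edge_nest_prob=1.0,
            nos2_edge_rate=0.0,
            cox2_nest_rate=0.01,
            cox2_edge_rate=0.0,
            cox2_foci_per_nest=0.0,
            pd1_fraction_of_cd8=0.3,
            epcam_edge_rate=0.0,
            cd44v6_focus_rate=0.5,
        ),
        "mixed": dict(
            cox2_focus_radius=140.0,
            nest_pockets_per_mm2=0.3,
            cd8_pockets_per_mm2=0.5,
            cd8_diffuse_per_mm2=4.0,
            cd8_core_allowed=True,
            nos2_edge_nest_prob=0.5,
            nos2_edge_rate=0.2,
            cox2_nest_rate=0.015,
            cox2_edge_rate=0.1,
            cox2_foci_per_nest=0.5,
            pd1_fraction_of_cd8=0.2,
            epcam_edge_rate=0.1,
            cd44v6_focus_rate=0.2,
        ),
    }

    def resolved(self) -> "TissueArchetypeSpec":
        if self.archetype not in ARCHETYPES:
            raise SyntheticDataError(f"unknown archetype {self.archetype!r}")
        if self.tumor_density <= 0 or self.stroma_density <= 0:
            raise SyntheticDataError("densities must be > 0")
        updates = {
            k: v
            for k, v in self._ARCHETYPE_DEFAULTS[self.archetype].items()
            if getattr(self, k) is None
        }
        return replace(self, **updates) if updates else self

    def positive_sd(self, marker: str) -> float:
        return self.positive_log_sd.get(marker, self.positive_log_sd_default)


def _place_discs(spec: TissueArchetypeSpec, rng: np.random.Generator):
    """Non-overlapping parent discs: list of (cx, cy, r, kind)."""
    w, h = spec.canvas
    area_mm2 = w * h / 1e6
    r_max = max(spec.nest_radius_range[1], spec.fragment_radius_range[1])
    if spec.big_nest_radius_range is not None:
        r_max = max(r_max, spec.big_nest_radius_range[1])
    if w < 2 * r_max or h < 2 * r_max:
        raise SyntheticDataError(
            f"canvas {spec.canvas} too small for one nest (max radius {r_max})"
        )
    n_parents = max(1, rng.poisson(spec.nest_intensity_per_mm2 * area_mm2))
    discs: list[tuple[float, float, float, str]] = []
    plan: list[str] = []
    if spec.big_nest_radius_range is not None:
        plan.append("desert")
    plan += [
        "fragment" if rng.random() < spec.fragment_fraction else "nest"
        for _ in range(n_parents)
    ]
    for kind in plan:
        if kind == "desert":
            lo, hi = spec.big_nest_radius_range
        elif kind == "fragment":
            lo, hi = spec.fragment_radius_range
        else:
            lo, hi = spec.nest_radius_range
        r = rng.uniform(lo, hi)
        for _try in range(500):
            cx = rng.uniform(r, w - r)
            cy = rng.uniform(r, h - r)
            if all(
                np.hypot(cx - ox, cy - oy) >= r + orr + spec.min_nest_separation
                for ox, oy, orr, _ in discs
            ):
                discs.append((float(cx), float(cy), float(r), kind))
                break
    if not any(k == "nest" for *_, k in discs):
        # guarantee at least one large nest so every archetype has a core
        r = float(np.mean(spec.nest_radius_range))
        discs.insert(0, (w / 2.0, h / 2.0, r, "nest"))
    return discs


def _uniform_in_disc(
    n: int, cx: float, cy: float, r: float, rng: np.random.Generator
) -> np.ndarray:
    rad = r * np.sqrt(rng.random(n))
    ang = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([cx + rad * np.cos(ang), cy + rad * np.sin(ang)])


def _outside_discs(xy: np.ndarray, discs) -> np.ndarray:
    out = np.ones(len(xy), dtype=bool)
    for cx, cy, r, _ in discs:
        out &= np.hypot(xy[:, 0] - cx, xy[:, 1] - cy) > r
    return out


def _sample_stroma(
    n: int, spec: TissueArchetypeSpec, discs, rng: np.random.Generator
) -> np.ndarray:
    """Uniform points on the canvas outside all discs (rejection)."""
    w, h = spec.canvas
    pts = []
    got = 0
    while got < n:
        m = max(64, int((n - got) * 1.8))
        cand = np.column_stack([rng.uniform(0, w, m), rng.uniform(0, h, m)])
        cand = cand[_outside_discs(cand, discs)]
        pts.append(cand)
        got += len(cand)
    return np.vstack(pts)[:n]


def simulate_tissue(
    spec: TissueArchetypeSpec, seed: int | None = None, sample_id: str = "S1"
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate one synthetic sample.

    Returns ``(cells, truth, geometry)``: the cell table (coordinates +
    marker intensities), the ground truth (per-cell marker flags, true
    phenotype, true region), and the realized geometry (discs, pockets,
    expected counts) for analytic cross-checks.
    """
    spec = spec.resolved()
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    w, h = spec.canvas
    area_mm2 = w * h / 1e6
    discs = _place_discs(spec, rng)
    disc_area_mm2 = sum(np.pi * r * r for _, _, r, _ in discs) / 1e6

    xs: list[np.ndarray] = []
    flags: dict[str, list[np.ndarray]] = {f: [] for f in TRUTH_FLAGS}
    regions: list[np.ndarray] = []

    def _emit(xy, **kw):
        n = len(xy)
        if n == 0:
            return
        xs.append(xy)
        for f in TRUTH_FLAGS:
            v = kw.get(f, False)
            flags[f].append(
                np.asarray(v, dtype=bool)
                if np.ndim(v)
                else np.full(n, bool(v))
            )
        reg = kw.get("region", "stroma")
        regions.append(
            np.asarray(reg, dtype=object) if np.ndim(reg) else np.full(n, reg, dtype=object)
        )

    # ---- tumor cells inside discs -------------------------------------
    foci_left = spec.cox2_max_foci
    expected_tumor = 0.0
    for cx, cy, r, kind in discs:
        if kind == "desert":
            # the desert territory: one whole nest, COX2+ wall to wall, at
            # its own cellularity; its diameter exceeds the 200-um census
            # range so desert neighborhoods have a COX2-pure interior
            density = spec.cox2_core_density
            plant_core = True
        elif kind == "nest" and rng.random() < spec.sparse_nest_prob:
            density = spec.sparse_nest_density
            plant_core = False
        else:
            density = spec.tumor_density
            plant_core = False
        expected_tumor += density * np.pi * r * r / 1e6
        n_cells = rng.poisson(density * np.pi * r * r / 1e6)
        xy = _uniform_in_disc(n_cells, cx, cy, r, rng)
        d_center = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
        if plant_core:
            # the desert territory spans the whole dominant nest, so its
            # boundary coincides with the steep nest/stroma density gradient
            is_cox2_core = np.ones(n_cells, dtype=bool)
        else:
            is_cox2_core = np.zeros(n_cells, dtype=bool)
        if kind == "fragment":
            region = np.full(n_cells, "fragment", dtype=object)
            is_edge = np.zeros(n_cells, dtype=bool)
        else:
            is_edge = (r - d_center) <= spec.nos2_edge_band
            region = np.where(is_edge, "nest_edge", "core").astype(object)
        nos2 = np.zeros(n_cells, dtype=bool)
        cox2 = rng.random(n_cells) < spec.cox2_nest_rate
        epcam = rng.random(n_cells) < spec.epcam_background_rate
        cd44 = rng.random(n_cells) < spec.cd44v6_background_rate
        if kind == "nest":
            # NOS2+ marginal foci: short arc segments of the edge band
            if spec.nos2_edge_rate and rng.random() < spec.nos2_edge_nest_prob:
                ang = np.arctan2(xy[:, 1] - cy, xy[:, 0] - cx)
                in_arc = np.zeros(n_cells, dtype=bool)
                half = np.deg2rad(spec.nos2_arc_halfwidth_deg)
                for _ in range(spec.nos2_arc_count):
                    a0 = rng.uniform(0, 2 * np.pi)
                    delta = np.angle(np.exp(1j * (ang - a0)))
                    in_arc |= np.abs(delta) <= half
                hot = is_edge & in_arc
                nos2 |= hot & (rng.random(n_cells) < spec.nos2_edge_rate)
                cox2 |= hot & (rng.random(n_cells) < spec.cox2_edge_rate)
                epcam |= hot & (rng.random(n_cells) < spec.epcam_edge_rate)
            # optional smaller COX2 foci (mixed archetype)
            for _ in range(min(rng.poisson(spec.cox2_foci_per_nest), foci_left)):
                max_off = r - spec.nos2_edge_band - spec.cox2_focus_radius
                if max_off <= 0:
                    continue
                foci_left -= 1
                off = max_off * np.sqrt(rng.random())
                a = rng.uniform(0, 2 * np.pi)
                fx, fy = cx + off * np.cos(a), cy + off * np.sin(a)
                in_focus = (
                    np.hypot(xy[:, 0] - fx, xy[:, 1] - fy) <= spec.cox2_focus_radius
                )
                cox2 |= in_focus & (rng.random(n_cells) < spec.cox2_focus_rate)
                cd44 |= in_focus & (rng.random(n_cells) < spec.cd44v6_focus_rate)
        # desert territory: the whole dominant nest is COX2+ (with CD44v6)
        cox2 |= is_cox2_core & (rng.random(n_cells) < spec.cox2_core_rate)
        cd44 |= is_cox2_core & (rng.random(n_cells) < spec.cd44v6_focus_rate)
        nos2 |= rng.random(n_cells) < spec.nos2_background_rate
        cox2 |= rng.random(n_cells) < spec.cox2_background_rate
        _emit(xy, tumor=True, nos2=nos2, cox2=cox2, epcam=epcam, cd44v6=cd44, region=region)

    # ---- stroma background cells --------------------------------------
    n_stroma = rng.poisson(spec.stroma_density * max(area_mm2 - disc_area_mm2, 0.0))
    xy = _sample_stroma(n_stroma, spec, discs, rng)
    _emit(
        xy,
        nos2=rng.random(n_stroma) < spec.nos2_background_rate,
        cox2=rng.random(n_stroma) < spec.cox2_background_rate,
        epcam=rng.random(n_stroma) < spec.epcam_background_rate,
        cd44v6=rng.random(n_stroma) < spec.cd44v6_background_rate,
        region="stroma",
    )

    # ---- CD8 pockets ---------------------------------------------------
    def _emit_pocket(px, py, radius, mean_cells, cd8_fraction):
        n_cells = rng.poisson(mean_cells)
        if n_cells == 0:
            return
        xy = _uniform_in_disc(n_cells, px, py, radius, rng)
        xy = xy[(xy[:, 0] >= 0) & (xy[:, 0] <= w) & (xy[:, 1] >= 0) & (xy[:, 1] <= h)]
        n_cells = len(xy)
        cd8 = rng.random(n_cells) < cd8_fraction
        cd3 = cd8 | (rng.random(n_cells) < spec.pocket_cd3only_fraction)
        _emit(
            xy,
            cd8=cd8,
            cd3=cd3,
            pd1=cd8 & (rng.random(n_cells) < spec.pd1_fraction_of_cd8),
            ifng=cd8 & (rng.random(n_cells) < spec.ifng_fraction_of_cd8),
            region=_pocket_regions(xy, discs, spec),
        )

    pockets: list[tuple[float, float, str]] = []
    nests = [d for d in discs if d[3] == "nest"]
    areas = np.array([r * r for _, _, r, _ in nests]) if nests else np.array([])
    # infiltration foci inside nests (fully-inflamed niche); at least two
    # foci whenever the archetype calls for any, so inflamed samples are
    # reliably T-cell rich
    if nests and spec.nest_pockets_per_mm2 > 0:
        # exactly two dense foci: reliable T-cell richness, while the
        # CD8+ fraction stays within the gradient gate's resolution
        for _ in range(2):
            cx, cy, r, _ = nests[rng.choice(len(nests), p=areas / areas.sum())]
            px, py = _uniform_in_disc(1, cx, cy, max(r - 100.0, 50.0), rng)[0]
            pockets.append((float(px), float(py), "nest"))
            _emit_pocket(
                px, py, spec.nest_pocket_radius, spec.nest_pocket_cells,
                spec.nest_pocket_cd8_fraction,
            )
    # stromal aggregates 50-100 um outside nest boundaries
    n_stroma_pockets = (
        max(2, rng.poisson(spec.cd8_pockets_per_mm2 * area_mm2))
        if spec.cd8_pockets_per_mm2 > 0
        else 0
    )
    for _ in range(n_stroma_pockets):
        placed = False
        if nests:
            for _try in range(200):
                cx, cy, r, _ = nests[rng.integers(len(nests))]
                gap = rng.uniform(50.0, 100.0)
                ang = rng.uniform(0, 2 * np.pi)
                px = cx + (r + gap) * np.cos(ang)
                py = cy + (r + gap) * np.sin(ang)
                if 0 <= px <= w and 0 <= py <= h and _outside_discs(
                    np.array([[px, py]]), discs
                )[0]:
                    placed = True
                    break
        if not placed:
            px, py = rng.uniform(0, w), rng.uniform(0, h)
        pockets.append((float(px), float(py), "stroma"))
        _emit_pocket(
            px, py, spec.cd8_pocket_radius, spec.cd8_cells_per_pocket,
            spec.pocket_cd8_fraction,
        )

    # ---- diffuse CD8 ---------------------------------------------------
    n_diff = rng.poisson(spec.cd8_diffuse_per_mm2 * area_mm2)
    if n_diff:
        if spec.cd8_core_allowed:
            xy = np.column_stack([rng.uniform(0, w, n_diff), rng.uniform(0, h, n_diff)])
        else:
            xy = _sample_stroma(n_diff, spec, discs, rng)
        region = _pocket_regions(xy, discs, spec)
        _emit(
            xy,
            cd8=True,
            cd3=True,
            pd1=rng.random(len(xy)) < spec.pd1_fraction_of_cd8,
            ifng=rng.random(len(xy)) < spec.ifng_fraction_of_cd8,
            region=region,
        )

    xy_all = np.vstack(xs)
    n = len(xy_all)
    flag_arr = {f: np.concatenate(flags[f]) for f in TRUTH_FLAGS}
    region_all = np.concatenate(regions)

    # lymphoid-aggregate truth: pocket CD3 clusters outside nests keep their
    # 'stroma' region unless large enough; refined below via pocket census
    cells = pd.DataFrame(
        {
            "cell_id": [f"c{i:06d}" for i in range(n)],
            "sample_id": sample_id,
            "x_um": xy_all[:, 0],
            "y_um": xy_all[:, 1],
        }
    )
    for f, marker in _MARKER_FOR_FLAG.items():
        pos = flag_arr[f]
        log_val = np.where(
            pos,
            rng.normal(spec.positive_log_mean, spec.positive_sd(marker), n),
            rng.normal(spec.negative_log_mean, spec.negative_log_sd, n),
        )
        cells[marker] = np.exp(log_val)

    truth = pd.DataFrame(
        {
            "cell_id": cells["cell_id"],
            "sample_id": sample_id,
            **{f"true_{f}": flag_arr[f] for f in TRUTH_FLAGS},
            "true_region": region_all,
        }
    )
    truth["true_phenotype"] = [
        phenotype_label(c, nn, x)
        for c, nn, x in zip(flag_arr["cd8"], flag_arr["nos2"], flag_arr["cox2"])
    ]

    geometry = {
        "discs": discs,
        "pockets": pockets,
        "canvas": spec.canvas,
        "disc_area_mm2": disc_area_mm2,
        "expected_tumor_cells": expected_tumor,
        "expected_stroma_cells": spec.stroma_density * max(area_mm2 - disc_area_mm2, 0.0),
    }
    return cells, truth, geometry


def _pocket_regions(xy: np.ndarray, discs, spec: TissueArchetypeSpec) -> np.ndarray:
    """True region for immune cells: inside a nest -> edge/core; inside a
    fragment -> fragment; otherwise stroma (aggregate truth is by design the
    pocket membership, handled by tests via geometry)."""
    region = np.full(len(xy), "stroma", dtype=object)
    for cx, cy, r, kind in discs:
        d = np.hypot(xy[:, 0] - cx, xy[:, 1] - cy)
        inside = d <= r
        if kind == "fragment":
            region[inside] = "fragment"
        else:
            region[inside & (r - d <= spec.nos2_edge_band)] = "nest_edge"
            region[inside & (r - d > spec.nos2_edge_band)] = "core"
    return region


def simulate_cohort(
    n_deceased: int = 12,
    n_alive: int = 12,
    seed: int = 0,
    true_hr: float = 3.0,
    alive_hazard_per_month: float = 0.01,
    horizon_months: float = 120.0,
    spec_overrides: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Multi-sample cohort: Deceased-like samples alternate immune_desert /
    stroma_restricted, Alive-like samples are fully_inflamed; survival times
    are exponential with a planted group hazard ratio and administrative
    censoring at ``horizon_months``.

    Returns (cells, truth, clinical)."""
    if n_deceased < 2 or n_alive < 2:
        raise SyntheticDataError("need >= 2 samples per group")
    rng = np.random.default_rng(seed)
    overrides = spec_overrides or {}
    cells_parts, truth_parts, clin_rows = [], [], []
    plan = [
        ("Deceased", "immune_desert" if i % 2 == 0 else "stroma_restricted", f"D{i+1:02d}")
        for i in range(n_deceased)
    ] + [("Alive", "fully_inflamed", f"A{i+1:02d}") for i in range(n_alive)]
    for group, archetype, sid in plan:
        spec = TissueArchetypeSpec(archetype=archetype, **overrides)
        sample_seed = int(rng.integers(0, 2**31 - 1))
        c, t, _ = simulate_tissue(spec, seed=sample_seed, sample_id=sid)
        cells_parts.append(c)
        truth_parts.append(t)
        hazard = alive_hazard_per_month * (true_hr if group == "Deceased" else 1.0)
        time = float(rng.exponential(1.0 / hazard))
        event = time <= horizon_months
        clin_rows.append(
            {
                "sample_id": sid,
                "group": group,
                "time_months": min(time, horizon_months),
                "event": event,
                "archetype": archetype,
            }
        )
    return (
        pd.concat(cells_parts, ignore_index=True),
        pd.concat(truth_parts, ignore_index=True),
        pd.DataFrame(clin_rows),
    )


def simulate_expression_cohort(
    n: int = 100,
    true_hr: float = 4.0,
    seed: int = 0,
    baseline_hazard_per_month: float = 0.02,
    horizon_months: float = 120.0,
    genes: tuple[str, str] = ("NOS2", "CD8A"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression-cohort test double for the validation stage.

    Two log-normal genes; the hazard is proportional to the planted
    median-split label of their ratio with hazard ratio ``true_hr``, so
    median dichotomization followed by the O/E hazard ratio estimates
    exactly the planted quantity. Returns (genes x samples matrix,
    clinical table with an er_status column)."""
    if n < 20:
        raise SyntheticDataError("need n >= 20 expression samples")
    rng = np.random.default_rng(seed)
    sample_ids = [f"GSM{i+1:04d}" for i in range(n)]
    num = np.exp(rng.normal(2.0, 0.6, n))
    den = np.exp(rng.normal(2.0, 0.6, n))
    expr = pd.DataFrame([num, den], index=list(genes), columns=sample_ids)
    ratio = num / den
    high = ratio > np.median(ratio)
    hazard = baseline_hazard_per_month * np.where(high, true_hr, 1.0)
    time = rng.exponential(1.0 / hazard)
    event = time <= horizon_months
    clinical = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "time_months": np.minimum(time, horizon_months),
            "event": event,
            "er_status": "negative",
            "group": np.where(event, "Deceased", "Alive"),
        }
    )
    return expr, clinical
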
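"""Intensity-gradient gating and phenotype calling.

Fluorescence intensity is gated per sample and per marker by a gradient
rule: from the marker's per-sample mean ``mu`` and sample standard deviation
``sigma`` (n-1 denominator), cells at or above ``mu + 2*sigma`` are *weak*
positive, ``mu + 4*sigma`` *moderate*, and ``mu + 6*sigma`` *strong*. The
gradient levels are nested (strong implies moderate implies weak). Cell
phenotypes are the joint CD8/NOS2/COX2 positivity state (eight labels); the
reference gate levels are NOS2 >= moderate, COX2 >= moderate, CD8 >= weak,
all configurable.

Thresholds are computed within each sample so slide-to-slide staining
variation does not leak across samples; because the cutoffs are affine in
the data, rescaling a sample's intensities by any positive constant leaves
every call unchanged.

Sample-level (whole-tumor) labels summarize the fraction of positive cells:
a sample is CD8+ when more than 4% of its cells are CD8+ (strict), and
NOS2/COX2 high when the positive fraction exceeds a configured cutoff. A
1-D two-means "natural break" finder is provided for users who want a
data-driven split, but it is never applied silently.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "PHENOTYPES",
    "MarkerThresholds",
    "GatingConfig",
    "GatingError",
    "compute_gradient_thresholds",
    "compute_sample_thresholds",
    "call_phenotypes",
    "assign_cell_phenotype",
    "positivity_table",
    "classify_sample",
    "classify_samples",
    "teff_mask",
    "natural_break_cutoff",
    "phenotype_label",
]

GRADIENT_LEVELS = ("weak", "moderate", "strong")

#: Canonical order of the eight joint phenotypes.
PHENOTYPES = tuple(
    f"CD8{c}NOS2{n}COX2{x}" for c in "-+" for n in "-+" for x in "-+"
)


class GatingError(ValueError):
    """Gating contract violation (too few cells, NaN intensity, ...)."""


@dataclass(frozen=True)
class MarkerThresholds:
    """Per-sample gradient cutoffs for one marker.

    ``weak <= moderate <= strong`` always; equality only when ``sd == 0``.
    """

    marker: str
    mean: float
    sd: float

    @property
    def weak(self) -> float:
        return self.mean + 2.0 * self.sd

    @property
    def moderate(self) -> float:
        return self.mean + 4.0 * self.sd

    @property
    def strong(self) -> float:
        return self.mean + 6.0 * self.sd

    def level(self, name: str) -> float:
        if name not in GRADIENT_LEVELS:
            raise GatingError(f"unknown gradient level {name!r}")
        return getattr(self, name)


@dataclass
class GatingConfig:
    """Gate levels and sample-classification cutoffs.

    ``cd8_high_fraction`` is the whole-sample T-cell abundance rule: a
    sample counts as CD8+ (T-cell high) when the CD8+ percentage of cells
    strictly exceeds it (default 4.0%).
    """

    nos2_positive_level: str = "moderate"
    cox2_positive_level: str = "moderate"
    cd8_positive_level: str = "weak"
    cd3_positive_level: str = "weak"
    pd1_positive_level: str = "weak"
    default_positive_level: str = "weak"  # for auxiliary markers (EPCAM, ...)
    cd8_high_fraction: float = 4.0
    sample_marker_high_cutoffs: dict = field(
        default_factory=lambda: {"NOS2": 0.5, "COX2": 2.0}
    )
    min_cells: int = 100

    def positive_level(self, marker: str) -> str:
        return {
            "NOS2": self.nos2_positive_level,
            "COX2": self.cox2_positive_level,
            "CD8": self.cd8_positive_level,
            "CD3": self.cd3_positive_level,
            "PD1": self.pd1_positive_level,
        }.get(marker, self.default_positive_level)


def compute_gradient_thresholds(
    intensities: np.ndarray, marker: str = ""
) -> MarkerThresholds:
    """Compute weak/moderate/strong cutoffs (mean + 2/4/6 sample SD)."""
    values = np.asarray(intensities, dtype=float)
    if values.ndim != 1:
        values = values.ravel()
    if values.size < 2:
        raise GatingError(f"need >= 2 intensities to gate marker {marker!r}")
    if not np.isfinite(values).all():
        raise GatingError(f"non-finite intensity for marker {marker!r}")
    if (values < 0).any():
        raise GatingError(f"negative intensity for marker {marker!r}")
    return MarkerThresholds(
        marker=marker, mean=float(values.mean()), sd=float(values.std(ddof=1))
    )


def compute_sample_thresholds(
    cells: pd.DataFrame, markers: tuple[str, ...] | list[str]
) -> dict[str, dict[str, MarkerThresholds]]:
    """Per-sample, per-marker thresholds over all cells of each sample."""
    out: dict[str, dict[str, MarkerThresholds]] = {}
    for sample_id, grp in cells.groupby("sample_id", sort=True):
        out[str(sample_id)] = {
            m: compute_gradient_thresholds(grp[m].to_numpy(), marker=m)
            for m in markers
        }
    return out


def phenotype_label(cd8: bool, nos2: bool, cox2: bool) -> str:
    return f"CD8{'+' if cd8 else '-'}NOS2{'+' if nos2 else '-'}COX2{'+' if cox2 else '-'}"


def _marker_positive(
    cells: pd.DataFrame,
    thresholds: dict[str, dict[str, MarkerThresholds]],
    marker: str,
    level: str,
) -> np.ndarray:
    """Vectorized `intensity >= per-sample cutoff` (inclusive boundary)."""
    if marker not in cells.columns:
        raise GatingError(f"missing marker intensity column {marker!r}")
    cutoffs = np.empty(len(cells))
    samples = cells["sample_id"].to_numpy()
    for sample_id in np.unique(samples):
        try:
            thr = thresholds[str(sample_id)][marker]
        except KeyError as exc:
            raise GatingError(
                f"no thresholds for marker {marker!r} in sample {sample_id!r}"
            ) from exc
        cutoffs[samples == sample_id] = thr.level(level)
    return cells[marker].to_numpy(dtype=float) >= cutoffs


def call_phenotypes(
    cells: pd.DataFrame,
    thresholds: dict[str, dict[str, MarkerThresholds]],
    gating: GatingConfig | None = None,
) -> pd.DataFrame:
    """Assign the eight-way CD8/NOS2/COX2 phenotype to every cell.

    Returns a copy of ``cells`` with a ``phenotype`` column plus nested
    gradient flags ``nos2_weak``/``nos2_moderate``/``nos2_strong`` (and the
    same for COX2 and CD8) supporting strong-signal ("NOS2s") analyses.
    """
    gating = gating or GatingConfig()
    out = cells.copy()
    for marker in ("NOS2", "COX2", "CD8"):
        for lvl in GRADIENT_LEVELS:
            out[f"{marker.lower()}_{lvl}"] = _marker_positive(
                cells, thresholds, marker, lvl
            )
    cd8 = _marker_positive(cells, thresholds, "CD8", gating.cd8_positive_level)
    nos2 = _marker_positive(cells, thresholds, "NOS2", gating.nos2_positive_level)
    cox2 = _marker_positive(cells, thresholds, "COX2", gating.cox2_positive_level)
    out["cd8_pos"] = cd8
    out["nos2_pos"] = nos2
    out["cox2_pos"] = cox2
    signs = np.where(cd8, "CD8+", "CD8-").astype(object)
    signs = signs + np.where(nos2, "NOS2+", "NOS2-")
    signs = signs + np.where(cox2, "COX2+", "COX2-")
    out["phenotype"] = pd.Categorical(signs, categories=list(PHENOTYPES))
    return out


def assign_cell_phenotype(
    cell: pd.Series | dict,
    thresholds: dict[str, MarkerThresholds],
    gating: GatingConfig | None = None,
) -> tuple[str, dict[str, bool]]:
    """Single-cell convenience wrapper: returns (phenotype, gradient flags)."""
    gating = gating or GatingConfig()
    flags: dict[str, bool] = {}
    for marker in ("NOS2", "COX2", "CD8"):
        if marker not in cell or not np.isfinite(float(cell[marker])):
            raise GatingError(f"missing marker intensity {marker!r}")
        thr = thresholds[marker]
        for lvl in GRADIENT_LEVELS:
            flags[f"{marker}{lvl}"] = float(cell[marker]) >= thr.level(lvl)
    cd8 = float(cell["CD8"]) >= thresholds["CD8"].level(gating.cd8_positive_level)
    nos2 = float(cell["NOS2"]) >= thresholds["NOS2"].level(gating.nos2_positive_level)
    cox2 = float(cell["COX2"]) >= thresholds["COX2"].level(gating.cox2_positive_level)
    return phenotype_label(cd8, nos2, cox2), flags


def positivity_table(
    cells: pd.DataFrame,
    thresholds: dict[str, dict[str, MarkerThresholds]],
    gating: GatingConfig | None = None,
    markers: tuple[str, ...] | list[str] | None = None,
    levels: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Boolean positivity per cell for arbitrary markers at their configured
    gate level (``levels`` overrides per marker)."""
    gating = gating or GatingConfig()
    if markers is None:
        some_sample = next(iter(thresholds.values()))
        markers = tuple(some_sample.keys())
    levels = levels or {}
    data = {
        m: _marker_positive(cells, thresholds, m, levels.get(m, gating.positive_level(m)))
        for m in markers
    }
    out = pd.DataFrame(data, index=cells.index)
    out.insert(0, "sample_id", cells["sample_id"].to_numpy())
    out.insert(0, "cell_id", cells["cell_id"].to_numpy())
    return out


@dataclass(frozen=True)
class SampleClass:
    sample_id: str
    label: str  # e.g. "CD8+NOS2-COX2+" or "unassigned"
    pct_positive: dict[str, float]
    n_cells: int


def classify_sample(
    called: pd.DataFrame, gating: GatingConfig | None = None
) -> SampleClass:
    """Whole-sample CD8/NOS2/COX2 label from one sample's phenotype calls.

    CD8+ iff the CD8+ cell percentage strictly exceeds ``cd8_high_fraction``
    (the >4% T-cell abundance rule); NOS2/COX2 high iff their positive
    percentage strictly exceeds the configured cutoff. Raw percentages are
    returned so users can re-draw their own natural breaks.
    """
    gating = gating or GatingConfig()
    sample_ids = called["sample_id"].unique()
    if len(sample_ids) != 1:
        raise GatingError("classify_sample expects cells of exactly one sample")
    n = len(called)
    pct = {
        "CD8": 100.0 * called["cd8_pos"].mean(),
        "NOS2": 100.0 * called["nos2_pos"].mean(),
        "COX2": 100.0 * called["cox2_pos"].mean(),
    }
    if n < gating.min_cells:
        warnings.warn(
            f"sample {sample_ids[0]!r} has {n} cells (< {gating.min_cells}); "
            "label set to 'unassigned'",
            stacklevel=2,
        )
        return SampleClass(str(sample_ids[0]), "unassigned", pct, n)
    cd8 = pct["CD8"] > gating.cd8_high_fraction
    nos2 = pct["NOS2"] > gating.sample_marker_high_cutoffs.get("NOS2", 2.0)
    cox2 = pct["COX2"] > gating.sample_marker_high_cutoffs.get("COX2", 2.0)
    return SampleClass(str(sample_ids[0]), phenotype_label(cd8, nos2, cox2), pct, n)


def classify_samples(
    called: pd.DataFrame, gating: GatingConfig | None = None
) -> pd.DataFrame:
    """Per-sample summary table of labels and positive-cell percentages."""
    rows = []
    for sample_id, grp in called.groupby("sample_id", sort=True):
        sc = classify_sample(grp, gating)
        rows.append(
            {
                "sample_id": sc.sample_id,
                "label": sc.label,
                "n_cells": sc.n_cells,
                **{f"pct_{m}": v for m, v in sc.pct_positive.items()},
            }
        )
    return pd.DataFrame(rows)


def teff_mask(
    cells: pd.DataFrame,
    thresholds: dict[str, dict[str, MarkerThresholds]],
    gating: GatingConfig | None = None,
) -> pd.Series:
    """Cytolytic T-effector mask: CD3+ and CD8+ and PD1-."""
    gating = gating or GatingConfig()
    cd3 = _marker_positive(cells, thresholds, "CD3", gating.cd3_positive_level)
    cd8 = _marker_positive(cells, thresholds, "CD8", gating.cd8_positive_level)
    pd1 = _marker_positive(cells, thresholds, "PD1", gating.pd1_positive_level)
    return pd.Series(cd3 & cd8 & ~pd1, index=cells.index, name="teff")


def natural_break_cutoff(values: np.ndarray, seed: int = 0) -> float:
    """Optional 1-D two-means break finder (midpoint between the two class
    means). Provided for drawing data-driven high/low sample cutoffs; never
    applied automatically."""
    from sklearn.cluster import KMeans

    v = np.asarray(values, dtype=float).reshape(-1, 1)
    if len(v) < 2 or np.ptp(v) == 0:
        raise GatingError("natural break needs >= 2 distinct values")
    km = KMeans(n_clusters=2, n_init=10, random_state=seed).fit(v)
    c = np.sort(km.cluster_centers_.ravel())
    return float(c.mean())
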
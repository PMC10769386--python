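"""Niche discovery: embed neighborhood profiles, cluster them, and compute
cluster-level statistics (composition, group prevalence ratios, phenotype
density-profile curves).

Neighborhood profiles (area-normalized ring densities, z-scored per feature)
are reduced to 2-D with UMAP and partitioned with adaptive k-means: k is
chosen to maximize mean silhouette over a seeded evaluation subsample unless
a fixed k (the reference configuration uses 17) is requested. When the cell
count exceeds ``subsample_n`` the UMAP is fitted on a seeded uniform
subsample and the remaining cells are placed by inverse-distance-weighted
k-nearest-neighbor interpolation of the fitted embedding in profile feature
space.

Cluster statistics mirror the downstream survival question: composition is
the percentage of each cluster's cells per phenotype; prevalence is the
percentage of each *sample's* cells per cluster (per-sample first, so large
samples do not dominate); the group ratio divides mean prevalence in
Deceased samples by mean prevalence in Alive samples, with explicit flags
for 0-denominator and 0/0 clusters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from spatialtme.gating import PHENOTYPES
from spatialtme.spatial_census import CensusResult, census_fractions, neighborhood_census

__all__ = [
    "NicheError",
    "NicheModel",
    "DensityProfileCurve",
    "profile_feature_matrix",
    "embed_profiles",
    "adaptive_kmeans",
    "cluster_composition",
    "prevalence_table",
    "prevalence_group_ratio",
    "phenotype_density_profile",
    "profile_ratio",
    "run_niche_analysis",
]


class NicheError(ValueError):
    pass


@dataclass
class NicheModel:
    embedding: np.ndarray  # (n, 2)
    labels: np.ndarray  # (n,) int, 1..k
    k: int
    seed: int
    subsample_idx: np.ndarray | None = None
    params: dict = field(default_factory=dict)
    silhouette_by_k: dict = field(default_factory=dict)


@dataclass
class DensityProfileCurve:
    """Mean (+/- SEM) within-ring phenotype fractions over a cluster's focal
    cells; NaN where no focal cell had a neighbor in the ring."""

    cluster: int
    mean_fraction: np.ndarray  # (P, R)
    sem: np.ndarray  # (P, R)
    n_contributing: np.ndarray  # (P, R) focal cells with non-empty ring
    phenotypes: tuple[str, ...]
    ring_edges: tuple[float, ...]


#: Default ring-distance taper: a niche is defined primarily by its
#: immediate neighborhood, so inner rings carry more weight than the
#: context rings further out.
DEFAULT_RING_TAPER = (1.6, 1.3, 1.0, 0.7, 0.45)


def profile_feature_matrix(
    census: CensusResult,
    mode: str = "density",
    standardize: bool = True,
    ring_taper: tuple[float, ...] | None = DEFAULT_RING_TAPER,
) -> np.ndarray:
    """Flattened, z-scored (per feature), ring-tapered profile matrix.

    ``ring_taper`` rescales each ring's features after standardization;
    pass None for untapered features.
    """
    X = census.feature_matrix(mode)
    if np.ptp(X) == 0:
        raise NicheError("constant profile matrix: no spatial structure to embed")
    if standardize:
        mu = X.mean(axis=0)
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - mu) / sd
    if ring_taper is not None:
        R = len(census.ring_edges) - 1
        w = np.asarray(ring_taper, dtype=float)
        if w.size != R:
            raise NicheError(f"ring_taper needs {R} weights")
        X = (X.reshape(len(X), -1, R) * w).reshape(len(X), -1)
    return X


def embed_profiles(
    X: np.ndarray,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    seed: int = 0,
    subsample_n: int = 50_000,
) -> tuple[np.ndarray, np.ndarray | None]:
    """2-D UMAP embedding of profile features, deterministic given seed.

    Returns (embedding, subsample_idx); subsample_idx is None when all cells
    were fitted directly.
    """
    import umap

    X = np.asarray(X, dtype=np.float32)
    n = X.shape[0]
    if n < 10:
        raise NicheError("need >= 10 profiles to embed")
    if np.ptp(X) == 0:
        raise NicheError("constant profile matrix")

    reducer = umap.UMAP(
        n_components=2,
        n_neighbors=n_neighbors,
        min_dist=min_dist,
        random_state=seed,
        n_jobs=1,
    )
    if n <= subsample_n:
        emb = reducer.fit_transform(X)
        return np.asarray(emb, dtype=np.float64), None

    rng = np.random.default_rng(seed)
    sub = np.sort(rng.choice(n, size=subsample_n, replace=False))
    emb_sub = np.asarray(reducer.fit_transform(X[sub]), dtype=np.float64)
    rest = np.setdiff1d(np.arange(n), sub, assume_unique=False)

    # place out-of-sample cells by inverse-distance weighted kNN in feature
    # space over the fitted subsample
    from pynndescent import NNDescent

    index = NNDescent(
        X[sub], n_neighbors=15, random_state=seed, n_jobs=1, verbose=False
    )
    k = min(10, subsample_n)
    nbr_idx, nbr_dist = index.query(X[rest], k=k)
    w = 1.0 / np.maximum(nbr_dist, 1e-12)
    w /= w.sum(axis=1, keepdims=True)
    emb = np.empty((n, 2), dtype=np.float64)
    emb[sub] = emb_sub
    emb[rest] = np.einsum("ij,ijd->id", w, emb_sub[nbr_idx])
    return emb, sub


def adaptive_kmeans(
    embedding: np.ndarray,
    k_range: tuple[int, int] = (2, 20),
    seed: int = 0,
    fixed_k: int | None = None,
    eval_subsample: int = 10_000,
    n_init: int = 10,
    silhouette_tolerance: float = 0.05,
) -> NicheModel:
    """Cluster the 2-D embedding with k-means; adaptive k by silhouette.

    Candidate k values come from ``k_range`` (inclusive); each is evaluated
    by mean silhouette on a seeded subsample of at most ``eval_subsample``
    cells, then the winning k is refitted on all cells. Because embeddings
    of tissue neighborhoods are near-continua, silhouette profiles are often
    flat in k; among partitions within ``silhouette_tolerance`` (relative)
    of the best score the *finest* one is chosen, so small recurrent niches
    are not absorbed into coarse territory splits. ``fixed_k`` bypasses
    adaptation (the reference configuration is fixed_k=17).
    """
    from sklearn.cluster import KMeans
    from sklearn.metrics import silhouette_score

    emb = np.asarray(embedding, dtype=np.float64)
    n = emb.shape[0]
    rng = np.random.default_rng(seed)
    sil_by_k: dict[int, float] = {}

    if fixed_k is not None:
        k = int(fixed_k)
        if k < 2:
            raise NicheError("fixed_k must be >= 2")
    else:
        lo, hi = int(k_range[0]), int(k_range[1])
        hi = min(hi, max(2, n // 10))
        candidates = [k for k in range(lo, hi + 1)]
        if not candidates:
            raise NicheError(f"empty k range {k_range} for n={n}")
        if n > eval_subsample:
            eval_idx = np.sort(rng.choice(n, size=eval_subsample, replace=False))
        else:
            eval_idx = np.arange(n)
        ev = emb[eval_idx]
        for k in candidates:
            km = KMeans(n_clusters=k, n_init=n_init, random_state=seed).fit(ev)
            if len(np.unique(km.labels_)) < 2:
                sil_by_k[k] = -1.0
                continue
            sil_by_k[k] = float(silhouette_score(ev, km.labels_))
        best = max(sil_by_k.values())
        cutoff = best - silhouette_tolerance * abs(best)
        k = max(kk for kk, s in sil_by_k.items() if s >= cutoff)

    # the full-data refit needs fewer restarts than model selection: the 2-D
    # embedding is dense and k-means converges to near-identical optima
    km = KMeans(n_clusters=k, n_init=max(3, n_init // 3), random_state=seed).fit(emb)
    labels = km.labels_.astype(int) + 1  # 1-based cluster ids
    return NicheModel(
        embedding=emb,
        labels=labels,
        k=int(len(np.unique(labels))),
        seed=seed,
        params={"k_range": tuple(k_range), "fixed_k": fixed_k, "n_init": n_init},
        silhouette_by_k=sil_by_k,
    )


def cluster_composition(
    phenotypes, labels, phenotype_order: tuple[str, ...] = PHENOTYPES
) -> pd.DataFrame:
    """k x 8 matrix: percentage of each cluster's cells per phenotype
    (rows sum to 100)."""
    ph = pd.Categorical(np.asarray(phenotypes, dtype=object), categories=list(phenotype_order))
    tab = pd.crosstab(np.asarray(labels), ph.codes)
    tab.columns = [phenotype_order[c] for c in tab.columns]
    tab = tab.reindex(columns=list(phenotype_order), fill_value=0)
    comp = 100.0 * tab.div(tab.sum(axis=1), axis=0)
    comp.index.name = "cluster"
    return comp


def prevalence_table(labels, sample_ids) -> pd.DataFrame:
    """samples x k matrix: percentage of each sample's cells per cluster
    (rows sum to 100)."""
    tab = pd.crosstab(np.asarray(sample_ids), np.asarray(labels))
    prev = 100.0 * tab.div(tab.sum(axis=1), axis=0)
    prev.index.name = "sample_id"
    prev.columns.name = "cluster"
    return prev


def prevalence_group_ratio(
    labels,
    sample_ids,
    clinical: pd.DataFrame,
    flag_high: float = 2.0,
    flag_low: float = 0.5,
) -> pd.DataFrame:
    """Per-cluster Deceased/Alive prevalence ratio.

    ratio_c = mean prevalence over Deceased samples / mean over Alive
    samples. Flags: 'ok', 'zero_denominator' (x/0 -> +inf), 'undefined'
    (0/0). Clusters with ratio > flag_high or < flag_low are marked
    enriched/depleted.
    """
    prev = prevalence_table(labels, sample_ids)
    groups = clinical.set_index("sample_id")["group"]
    missing = [s for s in prev.index if s not in groups.index]
    if missing:
        raise NicheError(f"sample {missing[0]!r} has no clinical record")
    dec = prev.loc[[s for s in prev.index if groups[s] == "Deceased"]]
    alv = prev.loc[[s for s in prev.index if groups[s] == "Alive"]]
    if len(dec) == 0 or len(alv) == 0:
        raise NicheError("need >= 1 sample per outcome group")
    m_dec = dec.mean(axis=0)
    m_alv = alv.mean(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = m_dec / m_alv
    flag = np.where(
        (m_alv == 0) & (m_dec == 0),
        "undefined",
        np.where(m_alv == 0, "zero_denominator", "ok"),
    )
    ratio = np.where(flag == "zero_denominator", np.inf, ratio)
    ratio = np.where(flag == "undefined", np.nan, ratio)
    out = pd.DataFrame(
        {
            "cluster": m_dec.index,
            "mean_prevalence_deceased": m_dec.to_numpy(),
            "mean_prevalence_alive": m_alv.to_numpy(),
            "ratio": ratio,
            "flag": flag,
        }
    )
    out["enriched_deceased"] = (out["ratio"] > flag_high) | (out["flag"] == "zero_denominator")
    out["enriched_alive"] = out["ratio"] < flag_low
    return out.reset_index(drop=True)


def phenotype_density_profile(
    cells: pd.DataFrame,
    labels: np.ndarray,
    target_cluster: int,
    ring_edges=None,
    phenotypes: tuple[str, ...] = PHENOTYPES,
    census: CensusResult | None = None,
) -> DensityProfileCurve:
    """Average within-ring phenotype fractions over a cluster's focal cells.

    A focal cell with an empty ring contributes nothing to that ring
    (undefined, not zero). Pass a precomputed full ``census`` to avoid
    recomputation.
    """
    labels = np.asarray(labels)
    mask = labels == target_cluster
    if not mask.any():
        raise NicheError(f"cluster {target_cluster} is empty")
    if census is None:
        census = neighborhood_census(
            cells, ring_edges=ring_edges, phenotypes=phenotypes, focal_mask=mask
        )
        frac = census.fractions
    else:
        frac = census.fractions[mask]
    with np.errstate(invalid="ignore"):
        n_contrib = np.isfinite(frac).sum(axis=0)
        mean = np.nanmean(np.where(np.isfinite(frac), frac, np.nan), axis=0)
        sd = np.nanstd(np.where(np.isfinite(frac), frac, np.nan), axis=0, ddof=1)
    sem = np.where(n_contrib > 1, sd / np.sqrt(np.maximum(n_contrib, 1)), np.nan)
    mean = np.where(n_contrib > 0, mean, np.nan)
    return DensityProfileCurve(
        cluster=int(target_cluster),
        mean_fraction=mean,
        sem=sem,
        n_contributing=n_contrib,
        phenotypes=tuple(phenotypes),
        ring_edges=census.ring_edges,
    )


def profile_ratio(curve_a: DensityProfileCurve, curve_b: DensityProfileCurve) -> np.ndarray:
    """Elementwise A/B of two profile curves (phenotype x ring).

    Zero denominators with positive numerators are +inf; undefined entries
    (NaN in either curve, or 0/0) propagate as NaN.
    """
    if curve_a.ring_edges != curve_b.ring_edges:
        raise NicheError("profile curves have mismatched ring edges")
    if curve_a.phenotypes != curve_b.phenotypes:
        raise NicheError("profile curves have mismatched phenotype order")
    a, b = curve_a.mean_fraction, curve_b.mean_fraction
    with np.errstate(divide="ignore", invalid="ignore"):
        r = a / b
    r = np.where((b == 0) & (a > 0), np.inf, r)
    r = np.where((b == 0) & (a == 0), np.nan, r)
    return r


def run_niche_analysis(
    cells_called: pd.DataFrame,
    clinical: pd.DataFrame,
    ring_edges=None,
    n_neighbors: int = 15,
    min_dist: float = 0.1,
    subsample_n: int = 50_000,
    k_range: tuple[int, int] = (2, 20),
    fixed_k: int | None = None,
    seed: int = 0,
    profile_mode: str = "density",
) -> dict:
    """End-to-end census -> UMAP -> adaptive k-means -> cluster statistics.

    Returns a dict with the census, model, composition, prevalence, and the
    Deceased/Alive prevalence-ratio table sorted by ratio (descending,
    +inf clusters ranked by Deceased prevalence)."""
    census = neighborhood_census(cells_called, ring_edges=ring_edges)
    X = profile_feature_matrix(census, mode=profile_mode)
    emb, sub = embed_profiles(
        X, n_neighbors=n_neighbors, min_dist=min_dist, seed=seed, subsample_n=subsample_n
    )
    model = adaptive_kmeans(emb, k_range=k_range, seed=seed, fixed_k=fixed_k)
    model.subsample_idx = sub
    comp = cluster_composition(cells_called["phenotype"], model.labels)
    prev = prevalence_table(model.labels, cells_called["sample_id"])
    ratio = prevalence_group_ratio(model.labels, cells_called["sample_id"], clinical)
    # rank clusters: finite ratios by value; +inf ties broken by Deceased
    # prevalence, exact-zero ties by Alive prevalence (the most group-
    # representative niche ranks as the extreme)
    r = ratio["ratio"].to_numpy(dtype=float)
    sort_key = np.where(np.isinf(r), 1e18 + ratio["mean_prevalence_deceased"], r)
    sort_key = np.where(r == 0.0, -1e-12 * ratio["mean_prevalence_alive"], sort_key)
    sort_key = np.where(np.isnan(r), 1.0, sort_key)
    ratio = ratio.assign(_key=sort_key).sort_values("_key", ascending=False).drop(columns="_key")
    return {
        "census": census,
        "model": model,
        "composition": comp,
        "prevalence": prev,
        "group_ratio": ratio.reset_index(drop=True),
    }
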
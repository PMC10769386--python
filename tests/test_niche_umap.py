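import numpy as np
import pandas as pd
import pytest

from spatialtme.gating import PHENOTYPES
from spatialtme.niche_umap import (
    NicheError,
    adaptive_kmeans,
    cluster_composition,
    embed_profiles,
    phenotype_density_profile,
    prevalence_group_ratio,
    prevalence_table,
    profile_feature_matrix,
    profile_ratio,
)
from spatialtme.spatial_census import neighborhood_census
from tests.conftest import make_cells

A, B = PHENOTYPES[0], PHENOTYPES[4]
EDGES = (0.0, 25.0, 50.0, 100.0, 150.0, 200.0)


def _two_population_profiles(rng, n_per=150, dim=40):
    """Profiles with all mass on phenotype A features vs phenotype B."""
    X = np.zeros((2 * n_per, dim))
    X[:n_per, :5] = rng.poisson(20, (n_per, 5))
    X[n_per:, 5:10] = rng.poisson(20, (n_per, 5))
    return X + rng.normal(0, 0.1, X.shape)


class TestEmbedding:
    def test_deterministic_given_seed(self, rng):
        X = _two_population_profiles(rng)
        e1, s1 = embed_profiles(X, seed=7)
        e2, s2 = embed_profiles(X, seed=7)
        np.testing.assert_array_equal(e1, e2)
        assert s1 is None and s2 is None  # no subsampling needed

    def test_separated_populations_stay_separated(self, rng):
        from sklearn.metrics import silhouette_score

        X = _two_population_profiles(rng)
        emb, _ = embed_profiles(X, seed=0)
        labels = np.repeat([0, 1], len(X) // 2)
        assert silhouette_score(emb, labels) > 0.5

    def test_subsample_projection_covers_all_cells(self, rng):
        X = _two_population_profiles(rng, n_per=300)
        emb, sub = embed_profiles(X, seed=1, subsample_n=200)
        assert emb.shape == (600, 2)
        assert sub is not None and len(sub) == 200
        # projected points land near their own population's fitted points
        from sklearn.metrics import silhouette_score

        labels = np.repeat([0, 1], 300)
        assert silhouette_score(emb, labels) > 0.5

    def test_constant_matrix_fatal(self):
        with pytest.raises(NicheError, match="constant"):
            embed_profiles(np.ones((50, 10)), seed=0)

    def test_too_few_profiles_fatal(self, rng):
        with pytest.raises(NicheError):
            embed_profiles(rng.normal(size=(5, 10)), seed=0)


class TestAdaptiveKMeans:
    def _blobs(self, rng, k=3, n_per=200, sep=50.0):
        centers = rng.uniform(-1, 1, (k, 2)) * sep
        pts = np.vstack([c + rng.normal(0, 1.0, (n_per, 2)) for c in centers])
        truth = np.repeat(np.arange(k), n_per)
        return pts, truth

    def test_recovers_three_planted_blobs(self, rng):
        from sklearn.metrics import adjusted_rand_score

        pts, truth = self._blobs(rng)
        model = adaptive_kmeans(pts, k_range=(2, 6), seed=0)
        assert model.k == 3
        assert adjusted_rand_score(truth, model.labels) == 1.0

    def test_fixed_k_overrides_adaptation(self, rng):
        pts, _ = self._blobs(rng, k=3, n_per=200)
        model = adaptive_kmeans(pts, k_range=(2, 6), seed=0, fixed_k=17)
        assert model.k == 17
        assert set(np.unique(model.labels)) == set(range(1, 18))

    def test_duplicated_points_share_labels(self, rng):
        pts, _ = self._blobs(rng, k=2, n_per=50)
        doubled = np.vstack([pts, pts])
        model = adaptive_kmeans(doubled, k_range=(2, 4), seed=0)
        np.testing.assert_array_equal(model.labels[: len(pts)], model.labels[len(pts) :])

    def test_empty_k_range_fatal(self, rng):
        pts, _ = self._blobs(rng)
        with pytest.raises(NicheError):
            adaptive_kmeans(pts, k_range=(5, 4), seed=0)

    def test_determinism(self, rng):
        pts, _ = self._blobs(rng)
        m1 = adaptive_kmeans(pts, k_range=(2, 5), seed=3)
        m2 = adaptive_kmeans(pts, k_range=(2, 5), seed=3)
        np.testing.assert_array_equal(m1.labels, m2.labels)


class TestClusterStats:
    def test_pure_cluster_composition(self):
        comp = cluster_composition([A, A, A], [1, 1, 1])
        assert comp.loc[1, A] == 100.0
        assert comp.loc[1].sum() == pytest.approx(100.0)

    def test_even_mixture(self):
        comp = cluster_composition([A, B, A, B], [1, 1, 1, 1])
        assert comp.loc[1, A] == 50.0 and comp.loc[1, B] == 50.0

    def test_planted_multinomial_recovered(self, rng):
        p = np.array([0.7, 0.2, 0.1])
        phenos = rng.choice([A, B, PHENOTYPES[7]], size=1000, p=p)
        comp = cluster_composition(phenos, np.ones(1000, dtype=int))
        for pheno, frac in zip([A, B, PHENOTYPES[7]], p):
            se = 100 * np.sqrt(frac * (1 - frac) / 1000)
            assert abs(comp.loc[1, pheno] - 100 * frac) <= 3 * se

    def test_prevalence_rows_sum_to_100(self, rng):
        labels = rng.integers(1, 5, 500)
        samples = rng.choice(["s1", "s2", "s3"], 500)
        prev = prevalence_table(labels, samples)
        assert np.allclose(prev.sum(axis=1), 100.0)


def _clinical(samples_deceased, samples_alive):
    return pd.DataFrame(
        {
            "sample_id": samples_deceased + samples_alive,
            "group": ["Deceased"] * len(samples_deceased) + ["Alive"] * len(samples_alive),
            "time_months": 10.0,
            "event": True,
        }
    )


class TestGroupRatio:
    def test_identical_prevalence_ratio_one(self):
        labels = np.tile([1, 2], 50)
        samples = np.repeat(["d1", "d2", "a1", "a2"], 25)
        out = prevalence_group_ratio(labels, samples, _clinical(["d1", "d2"], ["a1", "a2"]))
        assert np.allclose(out["ratio"], 1.0)

    def test_deceased_only_cluster_flagged_infinite(self):
        labels = np.array([1] * 50 + [2] * 50 + [1] * 50)  # cluster 2 only in d1
        samples = np.array(["d1"] * 100 + ["a1"] * 50)
        out = prevalence_group_ratio(labels, samples, _clinical(["d1"], ["a1"])).set_index("cluster")
        assert out.loc[2, "flag"] == "zero_denominator"
        assert np.isinf(out.loc[2, "ratio"])
        assert out.loc[2, "enriched_deceased"]

    def test_planted_fourfold_enrichment(self, rng):
        rows_l, rows_s = [], []
        for i, (grp, p2) in enumerate(
            [("d", 0.20)] * 6 + [("a", 0.05)] * 6
        ):
            lab = rng.choice([1, 2], size=2000, p=[1 - p2, p2])
            rows_l.append(lab)
            rows_s.append(np.full(2000, f"{grp}{i}"))
        labels = np.concatenate(rows_l)
        samples = np.concatenate(rows_s)
        clin = _clinical([f"d{i}" for i in range(6)], [f"a{i}" for i in range(6, 12)])
        out = prevalence_group_ratio(labels, samples, clin).set_index("cluster")
        se = 4.0 * np.sqrt(2 * (0.8 * 0.2 / 2000) / 6) / 0.05  # rough delta-method SE
        assert abs(out.loc[2, "ratio"] - 4.0) <= 3 * max(se, 0.2)

    def test_unknown_sample_fatal(self):
        with pytest.raises(NicheError, match="clinical"):
            prevalence_group_ratio(
                np.array([1, 1]), np.array(["s1", "zz"]), _clinical(["s1"], [])
            )

    def test_label_permutation_breaks_enrichment(self, rng):
        # planted difference beats the permutation null
        labels, samples = [], []
        for i in range(6):
            lab = rng.choice([1, 2], 1500, p=[0.75, 0.25])
            labels.append(lab)
            samples.append(np.full(1500, f"d{i}"))
        for i in range(6):
            lab = rng.choice([1, 2], 1500, p=[0.95, 0.05])
            labels.append(lab)
            samples.append(np.full(1500, f"a{i}"))
        labels = np.concatenate(labels)
        samples = np.concatenate(samples)
        ids = [f"d{i}" for i in range(6)] + [f"a{i}" for i in range(6)]
        true_clin = _clinical(ids[:6], ids[6:])
        obs = prevalence_group_ratio(labels, samples, true_clin)
        obs_stat = np.nanmax(np.abs(np.log(obs["ratio"].replace([np.inf], np.nan))))
        perm_stats = []
        for _ in range(50):
            perm = rng.permutation(ids)
            clin = _clinical(list(perm[:6]), list(perm[6:]))
            out = prevalence_group_ratio(labels, samples, clin)
            perm_stats.append(
                np.nanmax(np.abs(np.log(out["ratio"].replace([np.inf], np.nan))))
            )
        assert obs_stat > np.quantile(perm_stats, 0.95)


class TestDensityProfiles:
    def test_single_phenotype_tissue_fraction_one(self, rng):
        cells = make_cells(
            rng.uniform(0, 300, 120), rng.uniform(0, 300, 120), phenotype=[A] * 120
        )
        curve = phenotype_density_profile(cells, np.ones(120, dtype=int), 1, EDGES)
        ia = PHENOTYPES.index(A)
        occupied = curve.n_contributing[ia] > 0
        assert np.allclose(curve.mean_fraction[ia, occupied], 1.0)

    def test_planted_annulus_geometry(self):
        # phenotype B lives only at 30-40 um from the focal cell
        xs, ys, ph = [0.0], [0.0], [A]
        for ang in np.linspace(0, 2 * np.pi, 12, endpoint=False):
            for r in (30.0, 35.0, 40.0):
                xs.append(r * np.cos(ang))
                ys.append(r * np.sin(ang))
                ph.append(B)
        cells = make_cells(np.array(xs) + 100, np.array(ys) + 100, phenotype=ph)
        labels = np.array([1] + [2] * 36)
        curve = phenotype_density_profile(cells, labels, 1, EDGES)
        ib = PHENOTYPES.index(B)
        assert curve.mean_fraction[ib, 1] == pytest.approx(1.0)  # ring (25,50]
        # inner ring and outer rings have no neighbors at all -> undefined
        assert np.isnan(curve.mean_fraction[:, 0]).all()
        assert np.isnan(curve.mean_fraction[:, 3]).all()

    def test_empty_cluster_fatal(self, rng):
        cells = make_cells([0.0], [0.0], phenotype=[A])
        with pytest.raises(NicheError, match="empty"):
            phenotype_density_profile(cells, np.array([1]), 99, EDGES)


class TestProfileRatio:
    def _curve(self, frac):
        from spatialtme.niche_umap import DensityProfileCurve

        return DensityProfileCurve(
            cluster=1,
            mean_fraction=frac,
            sem=np.zeros_like(frac),
            n_contributing=np.ones_like(frac, dtype=int),
            phenotypes=PHENOTYPES,
            ring_edges=EDGES,
        )

    def test_equal_curves_unit_ratio(self):
        f = np.full((8, 5), 0.125)
        r = profile_ratio(self._curve(f), self._curve(f))
        assert np.allclose(r, 1.0)

    def test_zero_denominator_infinite(self):
        a = np.full((8, 5), 0.2)
        b = a.copy()
        b[0, 0] = 0.0
        r = profile_ratio(self._curve(a), self._curve(b))
        assert np.isinf(r[0, 0])

    def test_planted_tenfold_difference(self, rng):
        a = np.full((8, 5), 0.05)
        b = a.copy()
        a[2] = 0.5
        b[2] = 0.05
        r = profile_ratio(self._curve(a), self._curve(b))
        assert np.allclose(r[2], 10.0)

    def test_mismatched_rings_fatal(self):
        a = self._curve(np.full((8, 5), 0.1))
        b = self._curve(np.full((8, 5), 0.1))
        b.ring_edges = (0.0, 50.0, 200.0)
        with pytest.raises(NicheError, match="ring"):
            profile_ratio(a, b)


def test_profile_feature_matrix_standardization(rng):
    cells = make_cells(
        rng.uniform(0, 400, 200),
        rng.uniform(0, 400, 200),
        phenotype=rng.choice([A, B], 200),
    )
    census = neighborhood_census(cells, EDGES)
    X = profile_feature_matrix(census, mode="density", ring_taper=None)
    live = X.std(axis=0) > 0
    assert np.allclose(X[:, live].mean(axis=0), 0.0, atol=1e-9)
    assert np.allclose(X[:, live].std(axis=0), 1.0, atol=1e-9)
    # tapered features rescale each ring by its weight
    from spatialtme.niche_umap import DEFAULT_RING_TAPER

    Xt = profile_feature_matrix(census, mode="density")
    w = np.tile(DEFAULT_RING_TAPER, X.shape[1] // 5)
    np.testing.assert_allclose(Xt, X * w, atol=1e-12)
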
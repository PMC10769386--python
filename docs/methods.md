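# Methods

`spatialtme` implements a spatial single-cell analysis of multiplexed
immunofluorescence cell tables from ER-negative breast tumors, linking
tumor NOS2/COX2 expression and CD8+ T-cell geography to 5-year outcome.
This note records the models, the parameters that matter, the numerical
conventions, and what the synthetic-data generator does and does not
emulate.

## Input model

The unit of analysis is the segmented cell: an id, a sample id, x/y
centroid coordinates in micrometers, and one mean fluorescence intensity
per marker (NOS2, COX2, CD8, CD3, PD1, CK-SOX10, IFNγ, EpCAM, CD44v6).
Coordinates are Cartesian with arbitrary per-sample origin; all distances
are Euclidean in this frame. Intensities are in arbitrary units and are
never compared across samples; every gate is computed within a sample.
Missing intensities are rejected rather than imputed, because gating an
imputed intensity silently fabricates a phenotype.

## Intensity-gradient gating

For each sample and marker the gradient cutoffs are

    weak     = mean + 2·SD
    moderate = mean + 4·SD
    strong   = mean + 6·SD

with the arithmetic mean and the n−1 sample standard deviation taken over
all cells of the sample. Cells at or above a cutoff are positive at that
level (the boundary is inclusive, so calls are deterministic), and the
levels nest: strong ⊆ moderate ⊆ weak. The eight cell phenotypes are the
joint CD8±NOS2±COX2± states with reference gate levels NOS2 ≥ moderate,
COX2 ≥ moderate, CD8 ≥ weak (all configurable). Because the cutoffs are
affine in the data, multiplying a sample's intensities for one marker by
any positive constant changes no call — per-slide staining intensity drifts
out of the analysis by construction.

Two consequences of gating on the *mixture* (all cells, positives
included) are worth stating. First, with positive fraction p and positive
mean M far above background, the cutoff grows like
(p + k·sqrt(p(1−p)))·M; for the moderate gate (k = 4) the cutoff crosses
the positive mean once p exceeds roughly 6%, so a mean+k·SD rule can only
resolve marker-positive populations that are a few percent of the
sample's cells. This matches the per-sample %Cells scale at which these
markers occur in real cohorts, but it means the rule is *not* suitable
for abundant markers. Second, for a near-pure negative population the
weak gate flags the upper ~2σ tail (a fraction of a percent of cells) —
a floor on the false-positive rate that is inherent to the rule.
Accordingly, the abundant tumor marker (CK-SOX10, ~40% of cells) is gated
with the explicitly configured 1-D two-means "natural break" finder, which
is provided for exactly this purpose and is never applied silently.

Sample-level (whole-tumor) labels summarize positive-cell percentages: a
sample is T-cell high (CD8+) when strictly more than 4% of its cells are
CD8+; NOS2/COX2 high/low use configurable documented cutoffs (defaults
0.5% and 2.0% of cells). These labels are descriptive summaries; no
downstream statistic depends on them.

## Neighborhood census

Every cell's neighborhood profile counts its neighbors per phenotype in
five concentric rings, 0–25, 25–50, 50–100, 100–150 and 150–200 μm. Ring
membership is half-open, (lower, upper]; two distinct coincident cells
count in the innermost ring; the focal cell itself never counts; and
neighborhoods never span samples. Counts convert to densities by the
exact annulus area (cells/mm²) and to within-ring fractions by the ring's
total neighbor count; a ring with no neighbors has an *undefined* (NaN)
fraction, never zero, so averaged profile curves are not biased toward 0
in sparse tissue. No border correction is applied by default — profiles
near the tissue boundary are truncated, as in the source methodology.
The k-d-tree implementation is defined to agree integer-exactly with the
O(n²) all-pairs census, and the test suite holds it to that.

## Niche discovery (spatial UMAP)

Profiles are embedded in 2-D with UMAP and partitioned with k-means, so
clusters represent recurrent spatial *neighborhoods*, not expression
states. Choices that required judgement:

* **Feature construction.** The embedding input is the area-normalized
  density census (cells/mm²), flattened to 40 features (8 phenotypes ×
  5 rings), z-scored per feature, and ring-tapered (weights
  1.6/1.3/1.0/0.7/0.45 from the innermost ring out). Densities were
  chosen over raw counts (ring-width invariance) and over within-ring
  fractions: fraction profiles are dominated by small-denominator noise
  in the inner rings and discard the local-density context that
  defines, e.g., an immune desert, and on planted-architecture cohorts
  they dissolve the recoverable niches (maximum Deceased/Alive cluster
  ratio ~1.9 against >10 for densities). The taper encodes that a niche
  is defined primarily by its immediate neighborhood while the outer
  rings provide context; untapered features let the outer rings — whose
  area, and hence z-scored signal-to-noise, is largest — dominate, so
  clusters annex the 200-μm "halo" around a niche and dilute its
  composition. Count/sqrt-count/fraction modes and a flat taper remain
  selectable.
* **Subsampled fits.** Above `subsample_n` cells (default 50,000) the
  UMAP is fitted on a seeded uniform subsample; remaining cells are
  placed by inverse-distance-weighted 10-nearest-neighbor interpolation
  of the fitted embedding in profile feature space (pynndescent). This
  is deterministic given the seed and orders of magnitude faster than
  transforming ~5×10⁵ cells through UMAP itself; since every downstream
  statistic uses cluster labels rather than embedding coordinates, the
  interpolation only needs to place cells on the correct side of
  cluster boundaries.
* **Adaptive k.** Candidate k values (default 2–20) are scored by mean
  silhouette on a seeded evaluation subsample (≤10,000 cells). Because
  neighborhood-profile embeddings are near-continua, the silhouette
  profile in k is typically flat, and taking its plain maximum collapses
  to k = 2, absorbing small recurrent niches into coarse territory
  splits. The rule therefore selects the *finest* k whose silhouette is
  within 5% (relative) of the best score. With well-separated planted
  blobs the silhouette peak is sharp and the rule reduces to the plain
  argmax. A fixed k (the reference configuration is k = 17) bypasses
  adaptation.
* **Determinism.** The embed → cluster → statistics chain is a pure
  function of (input, seed); reruns are bitwise identical.

Cluster statistics: *composition* is the percentage of each cluster's
cells per phenotype (rows sum to 100); *prevalence* is the percentage of
each sample's cells per cluster (per-sample first, so large samples do
not dominate; a pooled mode exists); the *group ratio* divides mean
prevalence over Deceased samples by mean prevalence over Alive samples.
Clusters absent from one group are flagged (+inf for an empty Alive
denominator, NaN for 0/0) rather than silently divided. In ranked
reports, +inf clusters are ordered by their Deceased prevalence and
exact-zero clusters by their Alive prevalence — the most
group-representative niche ranks as the extreme — and the paper-style
"cluster #13 vs #12" contrast is the pair of extreme-ratio clusters.
Per-cluster phenotype density profiles average the within-ring fractions
over the cluster's focal cells (undefined rings contribute nothing) with
SEM across focal cells, and profile ratios divide two such curves
elementwise with explicit inf/NaN propagation.

## Density maps and hotspot statistic

Kernel density maps are binned Gaussian KDEs: cells are histogrammed on a
25-μm grid covering the bounding box padded by three bandwidths, then
smoothed with an isotropic Gaussian of 50 μm bandwidth (the recurring
cell-interaction scale in this analysis). Values are cells/mm² and the
grid integral reproduces the cell count up to kernel truncation (<2%).
The clustering scalar, `hotspot_fraction`, is the fraction of *tissue*
grid nodes (nodes within two bandwidths of any cell, so empty canvas
does not dilute it) with density strictly above mean + 2·SD, plus a
4-connected hotspot component count. It is a declared, reproducible
summary of map heterogeneity — a stand-in where the upstream analysis
reports "clustering" without a formula — and is validated as a
discriminator: Thomas-clustered point patterns score above intensity-
matched complete spatial randomness in ≥95% of paired simulations.

## Tissue regions

The tumor mask is the 12.5-μm grid occupancy of tumor-marker-positive
cells, morphologically closed with a 25-μm radius. Connected components
below 0.05 mm² are fragments (satellitosis); components at or above
0.05 mm² are nests. (The source definitions overlap on 0.05–0.1 mm²; a
single cut at 0.05 mm² is used and logged.) Nest cells within 50 μm of
the component boundary — located by sub-grid marching-squares contours —
form the edge band, flagged NOS2+ when ≥5% of its cells are NOS2
positive; the remainder is core. Outside the mask, single-linkage
clusters of ≥20 CD3+ cells at 30 μm linkage are lymphoid aggregates
(these two parameters are package defaults; the source describes the
structures qualitatively), and everything else is stroma. Every cell
receives exactly one label; region boundaries are accurate to about one
grid cell. Cores whose CD8+ density falls below 100 cells/mm² (~1% of
cells) carry an immune-desert flag. Boundary-gap statistics report, per
lymphoid aggregate, the distance from its centroid and from its nearest
member cell to the nearest nest boundary. Pathologist GeoJSON
annotations, when supplied, override derived labels.

## Cohort statistics and survival

Sample-level ratios divide positive-cell counts (NOS2/CD8, COX2/CD8 and
the CD44v6/EpCAM stemness variants; a CD3+CD8+PD1− effector variant uses
the cytolytic mask as denominator). Zero denominators are flagged, never
silently divided. Group comparisons use Mann-Whitney (exact null for
combined n ≤ 20 without ties, mid-rank normal approximation with tie
correction otherwise) or Welch's t; correlations are Pearson r/r² with
the t-distribution p-value.

Survival analysis is the classical Kaplan-Meier toolkit, authored
in-package: product-limit curves per group and, from the pooled 2×2 risk
tables at each distinct event time, O₁/E₁ observed-over-expected events,
giving

    HR = (O1/E1)/(O2/E2),  95% CI = exp(log HR ± 1.96·sqrt(1/E1 + 1/E2)),

the log-rank statistic (O1−E1)²/V with the hypergeometric variance V, and
the Gehan-Breslow-Wilcoxon variant weighting each event time by the
number at risk. Swapping the groups inverts the HR exactly; rescaling
time changes nothing. A Cox model is deliberately *not* the reference —
the O/E construction is the named procedure this analysis standardizes
on — though lifelines serves as an independent cross-check in the tests.
Five-year analyses administratively censor at 60 months before testing.
This horizon matters statistically, not just clinically: with full
follow-up of an exponential cohort at HR 3 the O/E estimator is biased
low (late risk sets are dominated by the low-hazard group), whereas under
the 5-year design it is calibrated (simulation: mean ≈ 2.96, 95% CI
coverage ≈ 0.97 at n = 200/arm).

The validation-cohort stage reads a gene-expression matrix (GEO
series-matrix text dialect or plain TSV) with its clinical table,
restricts to ER-negative samples when an ER-status column is configured,
forms per-sample expression ratios (e.g. NOS2/CD8A) on the matrix's
native scale (a logged choice — the upstream scale is not specified),
dichotomizes at the median (ties low) and runs the same KM/HR machinery.

## Synthetic data: what it emulates, and what it does not

The generator is the package's study-conditions module: every stage's
tests run against tissues whose ground truth is known by construction.

**Geometry.** Tumor nests are non-overlapping discs from a Poisson parent
process (radius 200–300 μm, ~1 parent/mm², 30% small fragments of
80–120 μm) on a 2.8×2.8 mm canvas; tumor cells fill discs at
4500 cells/mm² (a quarter of nests are sparse, 2500/mm², in every
archetype) and stroma fills the remainder at 1700/mm², for ~15–18,000
cells per sample. Non-overlap keeps true region labels (fragment, edge,
core, stroma) analytically exact.

**Architectures.** The three planted immune architectures differ only in
where their marker-decorated niches sit; all structural elements (nests,
sparse nests, stromal T-cell aggregates, faint NOS2 edge arcs, diffuse
CD8) occur in every archetype so that generic tissue does not separate
the outcome groups:

* *fully_inflamed* (Alive-like): two large, dense CD8+ infiltration
  foci (radius 150 μm, ~1000 cells, 95% CD8+) placed *inside* nests —
  deep-core infiltration — plus stromal aggregates and faint edge arcs.
* *stroma_restricted* (Deceased-like): CD8+ aggregates only in stroma,
  50–100 μm outside nest boundaries; NOS2+/COX2+ arc segments (two 60°
  arcs per nest at 30% positivity) on the nest edges with EpCAM; no
  in-nest foci.
* *immune_desert* (Deceased-like): one dedicated nest (190–220 μm
  radius, 5000 cells/mm²) that is COX2+ territory boundary-to-boundary
  (98% positivity, with CD44v6), so its diameter exceeds the 200-μm
  census range and desert neighborhoods have a COX2-pure interior; CD8
  is diffuse background only, leaving core CD8+ density far below the
  100 cells/mm² desert definition.

**Intensities.** Each marker is a two-component log-normal mixture:
negatives LogNormal(log 5, 0.5), positives LogNormal(log 200, 0.1–0.15).
Planted positive fractions stay within the few-percent range the
mean+k·SD mixture gate can resolve (see Gating), so the gate recovers
≥98% of planted phenotypes by construction — a property the tests
assert, not assume.

**Cohorts.** `simulate_cohort` draws Deceased-like samples alternating
immune_desert / stroma_restricted and Alive-like samples fully_inflamed
(default 12+12, mirroring a ~20-sample cohort), with exponential survival
times at a planted group hazard ratio (default 3, Alive hazard
0.01/month) and administrative censoring at 120 months.
`simulate_expression_cohort` plants a median-split hazard ratio on a
two-gene log-normal matrix so the expression-ratio pipeline estimates
exactly its planted quantity.

**What passing tests do and do not show.** The generator produces
circular nests, two-component intensity mixtures, and noise-free
segmentation; real tissue has irregular morphology, staining gradients,
autofluorescence, segmentation errors and cell-size variation. Passing
the planted-recovery tests therefore demonstrates that the *algorithms*
are correct and that the pipeline can recover architectures of the
planted effect sizes — not that real cohorts of this size yield the same
power. Cohort-level image-derived percentages from the motivating study
are not reproducible at desk scale (the raw images are not public), which
is why acceptance is property-based.

## Problem sizes

Default test and acceptance runs use: 50 random point sets (n ≤ 2000)
for census oracle equivalence; 10⁵ intensities for the gating closed
form; a 24-sample, ~4×10⁵-cell cohort (UMAP fitted on a 30,000-cell
subsample) for end-to-end niche recovery; 500 replicates at n = 200/arm
for hazard-ratio calibration; 10⁴ replicates for the Welch type-I rate;
and 100 paired patterns (n = 2000) for hotspot discrimination.

## Known limitations

* Whole-sample NOS2/COX2 high/low labels depend on documented cutoffs,
  not on automatic break detection; with the default synthetic
  parameters some stroma-restricted samples fall below the COX2 cutoff.
* The adaptive-k rule targets niche resolution, not parsimony; users
  wanting the most compact description should pass a fixed k.
* Region derivation is raster-based; areas and boundary distances carry
  grid-resolution error (12.5 μm default).
* The hotspot scalar is a heuristic summary; it is validated as a
  discriminator, not as an estimator of any process parameter.
* Edge-of-canvas censuses are truncated (no border correction), matching
  the source method but biasing outer-ring densities low within ~200 μm
  of the tissue boundary.
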
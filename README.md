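# spatialtme

Spatial single-cell analysis of tumor NOS2/COX2 expression and CD8+ T-cell
geography in multiplexed immunofluorescence data from ER-negative breast
cancer, linked to 5-year outcome.

## The problem

In ER− breast tumors, elevated tumor expression of inducible nitric oxide
synthase (NOS2) and cyclo-oxygenase 2 (COX2) predicts poor survival, and the
*spatial* arrangement of CD8+ T cells relative to these enzymes distinguishes
three immune architectures: fully inflamed tumors (CD8+ cells deep in the
tumor core), inflamed tumors with stroma-restricted CD8+ cells near NOS2+
margins, and COX2+ immune deserts with almost no CD8+ cells. `spatialtme`
implements the full analysis pipeline that quantifies this geography from
per-cell tables exported by image-analysis software (HALO/QuPath-style: cell
id, sample id, x/y in μm, mean intensity per marker):

1. **Gating** — per-sample intensity-gradient cutoffs at mean + 2/4/6 SD
   (weak / moderate / strong) and the eight joint CD8±NOS2±COX2± cell
   phenotypes; whole-sample labels via the >4% T-cell abundance rule.
2. **Neighborhood census** — per-cell counts of each phenotype in rings of
   0–25, 25–50, 50–100, 100–150, 150–200 μm, as counts, cells/mm², or
   within-ring fractions; 50-μm fixed-radius nearest-neighbor counts.
3. **Niche discovery (spatial UMAP)** — UMAP embedding of the census
   profiles, adaptive k-means clustering, cluster composition, per-sample
   cluster prevalence, Deceased/Alive prevalence ratios, per-cluster
   phenotype density-profile curves and their ratios.
4. **Density maps** — Gaussian kernel density heat maps per marker and a
   hotspot-fraction clustering scalar.
5. **Regions** — tumor fragments (<0.05 mm²), nests with NOS2±-flagged
   50-μm edge bands and cores, lymphoid aggregates, stroma; per-region
   composition, immune-desert flags (<100 CD8+ cells/mm²), and
   tumor-to-lymphoid boundary-gap distances.
6. **Cohort statistics** — positive-cell-count ratios (NOS2/CD8, COX2/CD8,
   NOS2/EpCAM, COX2/CD44v6, ...), Mann-Whitney/Welch comparisons, Pearson
   correlations, Kaplan-Meier curves with the Mantel-Haenszel O/E hazard
   ratio HR = (O₁/E₁)/(O₂/E₂), log-rank and Gehan-Breslow-Wilcoxon tests,
   and a gene-expression validation stage (series-matrix input, ratio
   dichotomized at the median, 60-month horizon).
7. **Synthetic data** — generators that plant the three architectures with
   full ground truth (true phenotypes, regions, survival hazards), used by
   every test.

See `docs/methods.md` for models, parameter choices and limitations.

## Worked example

Simulate a small cohort (4 Deceased-like, 4 Alive-like samples), gate, and
compare NOS2/CD8 ratios and survival:

```python
import numpy as np
from spatialtme.synthetic_data import simulate_cohort
from spatialtme import gating
from spatialtme.cohort_stats import group_compare, km_hazard, sample_ratios

cells, truth, clinical = simulate_cohort(4, 4, seed=7)  # ~140,000 cells
thr = gating.compute_sample_thresholds(cells, ("NOS2", "COX2", "CD8", "CD3", "PD1"))
called = gating.call_phenotypes(cells, thr)
pos = gating.positivity_table(called, thr, markers=("NOS2", "CD8"))
ratios = sample_ratios(pos, ratios=(("NOS2", "CD8"),)).merge(
    clinical[["sample_id", "group"]], on="sample_id"
)
print(ratios[["sample_id", "group", "pct_NOS2", "pct_CD8", "ratio_NOS2_CD8"]])
```

```
sample_id    group  pct_NOS2  pct_CD8  ratio_NOS2_CD8
      A01    Alive     0.282   10.771           0.026
      A02    Alive     0.554   10.356           0.053
      A03    Alive     0.294   11.821           0.025
      A04    Alive     0.186   10.963           0.017
      D01 Deceased     0.185    0.292           0.633
      D02 Deceased     0.798    2.298           0.347
      D03 Deceased     0.170    0.327           0.519
      D04 Deceased     0.722    1.949           0.370
```

Alive-like samples are T-cell rich (>10% CD8+ cells, well above the 4%
abundance rule); Deceased-like samples carry systematically higher
NOS2/CD8 ratios — low CD8 infiltration relative to NOS2 burden:

```python
dec = ratios.loc[ratios.group == "Deceased", "ratio_NOS2_CD8"]
alv = ratios.loc[ratios.group == "Alive", "ratio_NOS2_CD8"]
stat, p = group_compare(dec, alv)          # U = 16.0, exact p = 0.0286
res = km_hazard(
    clinical.time_months, clinical.event, clinical.group,
    group_order=("Deceased", "Alive"), horizon_months=60.0,
)
# res.hr = 1.672, 95% CI (0.32, 8.74) — 8 samples give a wide interval
```

The Mann-Whitney exact p of 0.0286 says the ratio separation is real even in
this tiny cohort; the hazard ratio points the right way but needs the full
cohort size for precision. The same flow runs from the shell:

```
spatialtme simulate --seed 7 --out run/
spatialtme all --seed 7 --out run/ --cells run/cells.csv --clinical run/clinical.csv
```

which writes per-stage CSVs (phenotypes, census, niche embedding/composition/
prevalence/group-ratio tables, hotspots, regions, ratios, KM curves) plus a
`manifest.json` recording config, seed, input digests and timings.

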
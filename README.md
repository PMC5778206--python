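# salamivision

Quantification of visible fat in images of sliced dry-cured salami.

The visible fat of a salami slice — the white particles embedded in the
red meat matrix — drives consumer perception and correlates with the
chemically extractable fat content, but chemical (Soxhlet) analysis is
slow, destructive and blind to particle size and shape. `salamivision`
implements a cheap image-analysis alternative for food scientists and
quality-control labs: photograph slices on a dark backdrop, segment the
fat particles, and report directly interpretable morphology.

## What it computes

For each slice image (calibrated with a `cm_per_pixel` scale):

* slice area *A*ₛ (cm²), particle count *n* and density *n*/*A*ₛ;
* per-particle area *AF*ᵢ, perimeter *P*ᵢ and **roundness**

  *RF*ᵢ = *P*ᵢ² / (4π·*AF*ᵢ),

  which is 1 for a perfect circle and grows with elongation;
* **visible fat content**

  VFC (%) = 100 · Σᵢ *AF*ᵢ / *A*ₛ ;
* a ten-class particle-area frequency distribution (0–0.1 cm² up to ≥5 cm²).

Replicate images of one sample aggregate to mean ± SD. The statistical
layer provides one-way ANOVA with Duncan's multiple range test (compact
letter displays per statistic), PCA on the correlation matrix of the
per-sample features, and the OLS regression of visible against
chemically measured fat (*R*²).

The segmentation chain is: RGB → 256-level grayscale (BT.601 luma) →
percentile contrast stretch → median filter → slice extraction
(multi-level Otsu against the dark backdrop, largest component, holes
filled) → Otsu threshold inside the slice → morphological closing with
a square structuring element → small-object removal → 8-connected
labelling. A synthetic phantom generator with exact ground truth makes
every stage testable without photographs.

## Worked example

Generate a small phantom study (4 samples × 5 replicate images), measure
it, and summarize:

```sh
salamivision generate run/images --samples 4 --replicates 5 --seed 7
salamivision measure run/images run/results --cm-per-pixel 0.02
salamivision summarize run/results/measurements.csv run/results
```

or equivalently in Python:

```python
from salamivision import PipelineConfig, default_study_specs, generate_study
from salamivision.reporting import measure_directory, summarize_run

specs = dict(list(default_study_specs(0).items())[:4])
generate_study("run/images", specs=specs, replicates=5, seed=7)
measure_directory("run/images", "run/results", PipelineConfig(), cm_per_pixel=0.02)
summary = summarize_run("run/results/measurements.csv", "run/results")
```

`run/results/summary_table.csv` then contains (selected columns):

```
sample  n_replicates  n_per_area_mean  af_mean_cm2_mean  vfc_pct_mean  vfc_pct_sd  vfc_pct_letters
     A             5            0.941             0.094         8.695       0.424                a
     B             5            0.859             0.115         9.705       0.219                b
     C             5            0.783             0.130        10.129       0.975                b
     D             5            1.109             0.102        11.117       0.646                c
```

Sample A averages 0.94 particles per cm² of slice with a mean particle
area of 0.094 cm² and a visible fat content of 8.7 ± 0.4 %; the Duncan
letters say A and D are separable from every other sample at p < .05
while B and C are not separable from each other. The generator's ground
truth for these four samples was 8.73 / 9.73 / 10.15 / 11.15 % VFC —
each recovered well within one percentage point. The output directory
also holds per-sample area-class histograms (CSV + bar chart), PCA
loadings/scores with scree and biplot figures, and — when a chemical
fat table is supplied via `--chemical-csv` — the visible-vs-chemical
regression scatter with its *R*².

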
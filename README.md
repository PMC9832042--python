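# cartimorph

Image-derived quantification of articular-cartilage aging: a cartilage
**surface-roughness index**, **53-descriptor nuclear morphometry** with
PCA-loading ranking (nuclear eccentricity as the aging marker), **per-cell
fluorescence quantification**, and the regressions linking nuclear shape,
age group, and marker expression — exercised end-to-end on a synthetic
microscopy cohort with recorded ground truth.

It is written for researchers quantifying cartilage degeneration and
chondrocyte nuclear mechanics from histology and immunofluorescence images
(e.g. knee-osteoarthritis aging studies in mice or human donor tissue), and
for anyone who wants the same measurements on other thin-tissue imagery.

## The quantities

**Surface roughness.** From a binary tissue mask, the top surface contour
(x_i, y_i) is extracted per column and fitted with a degree-4 polynomial
ŷ(x). The index is

    E = mean_i |y_i − ŷ(x_i)|        (mean discrepancy, px)
    L = ‖(x_n, y_n) − (x_1, y_1)‖    (edge-to-edge cartilage length, px)
    R = E / L                         (dimensionless; rises with degeneration)

**Nuclear eccentricity.** For each segmented nucleus, from the eigenvalues
λ_max ≥ λ_min of the pixel covariance matrix,

    e = sqrt(1 − λ_min / λ_max) ∈ [0, 1)

(0 = round, →1 = elongated; aged chondrocyte nuclei are less round). It is
one of exactly 53 shape/geometry descriptors per nucleus (23 classical
measures + 30 Zernike moment magnitudes, orders 0–9).

**Per-cell intensity.** Integrated density = Σ pixel values above a
negative-control threshold in one marker channel, divided by the number of
DAPI-segmented nuclei in the image; fields of view are sampled randomly per
sample and averaged per sample (n = samples).

**Statistics.** Features are z-scored; PCA loadings are the Pearson
correlations between each variable and each component score; contributors
are ranked by |loading|. Age trends are OLS on the ordinal group code
(young = 0, middle = 1, aged = 2). The marker model is
`marker ~ age + eccentricity`, with a predictor's *independent contribution*
measured by its last-added ΔR² (partial R²).

See `docs/methods.md` for conventions, the synthetic-cohort law, and
limitations.

## Worked example

```python
from cartimorph import CohortConfig, PipelineConfig, run_pipeline

cohort = CohortConfig(seed=1)          # 3 age groups × 5 samples × 5 images
config = PipelineConfig(out_dir="demo_out", seed=1, simulate=cohort.to_dict())
report = run_pipeline(config)

print(report["roughness"]["trend_slope"])          # 0.005735...
print(report["pca"]["top_contributors_pc1"][:3])   # strongest PC1 loadings
print(report["pca"]["silhouette_young_aged"])      # 0.3168...
```

With seed 1 this simulates a 15-sample cohort (679 nuclei), and the report
shows:

- roughness age-trend slope **+0.0057 per group step** (p < 1e-6): the
  surface-roughness index rises from young to aged, tracking the programmed
  amplitudes 1 → 2 → 4 px;
- eccentricity age-trend slope **+0.083 per group step**: nuclei elongate
  with age (programmed group means 0.57 → 0.67 → 0.77);
- `eccentricity` ranks **7th of 53** by |PC1 loading| and the young/aged
  silhouette on PC1–PC2 is **0.32** — the two extreme age groups form
  separated clusters;
- the marker model recovers negative age and eccentricity coefficients
  (marker intensity falls with both), with each predictor's partial R²
  quantifying its contribution beyond the other.

All outputs land in `demo_out/`: per-stage CSV tables (`roughness.csv`,
`nuclei_features.csv`, `sample_features.csv`, `intensity.csv`,
`pca_loadings.csv`, ...), `regressions.json`, and a `report.json` with
provenance (config hash, seed, version). The same stages are available from
the shell:

```bash
cartimorph simulate --out cohort_dir --seed 1
cartimorph run --config pipeline.yaml
cartimorph roughness --masks cohort_dir --metadata cohort_dir/metadata.csv --out out
cartimorph nuclei    --images cohort_dir --metadata cohort_dir/metadata.csv --out out
```

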
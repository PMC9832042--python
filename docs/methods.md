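# Methods

`cartimorph` quantifies three image-derived readouts of articular-cartilage
aging — surface roughness, nuclear shape, and per-cell marker expression —
and the statistics linking them. Because no public image data accompany
studies of this design, a synthetic cohort generator with recorded ground
truth stands in for the microscopy, and every analysis stage is validated
against that truth.

## Surface-roughness index

The input is a binary mask of the medial-tibia cartilage (tissue = foreground,
row 0 = image top). The articular surface is the topmost foreground pixel per
column of the largest connected component; columns inside the tissue span with
no foreground (torn sections) are excluded rather than interpolated. A
polynomial of degree exactly 4 is least-squares fitted to the (x, y) contour
— degree 4 is flexible enough for the gentle curvature of a healthy tibial
plateau while treating higher-frequency deviation as roughness. The statistic
is

- error `E` = mean |residual| of the contour about the quartic (px). Mean
  absolute deviation is the primary metric ("mean discrepancy"); RMS is
  available behind `metric="rms"` for sensitivity analysis.
- length `L` = Euclidean distance between the contour endpoints (px), i.e.
  the edge-to-edge extent of the medial tibia, not arc length.
- roughness `R = E / L`, dimensionless, invariant under uniform image
  rescaling and vertical translation.

Numerics: x is centred and scaled before solving (a degree-4 Vandermonde on
raw pixel columns is ill-conditioned) and coefficients are reported in the
original pixel domain. Contours need at least 6 points so the fit retains
residual degrees of freedom. Per-sample `R` is the mean over that sample's
masks; the age trend is an OLS of per-sample `R` on the ordinal group code
(young = 0, middle = 1, aged = 2).

## Nuclear morphometry

Nuclei are segmented from a DAPI-style grayscale image by global Otsu
thresholding, hole filling, 8-connected labeling and an area filter
(default 50–5000 px²). Watershed declumping is deliberately absent: cartilage
chondrocytes are sparse, and the synthetic nuclei never touch by
construction; a flag is reserved should real, touching nuclei be processed.
Border-touching objects are flagged but retained.

Each nucleus is summarised by a frozen roster of exactly 53 descriptors:
23 geometry measures — area, perimeter (Crofton, 4 directions), form factor
4πA/P² (clipped at 1, since the Crofton perimeter of small rasterised disks
can push the ratio marginally above 1), solidity, extent, Euler number,
eccentricity, major/minor axis lengths, orientation, compactness,
equivalent diameter, max/mean/median radius (from the Euclidean distance
transform), min/max Feret diameters (convex hull of pixel corners),
bounding-box area and aspect ratio, centroid x/y, convex area (pixelised
convex hull), and 1 − form factor — plus the magnitudes of the 30 Zernike
moments of orders n = 0–9 (all valid m), computed on the unit disk
circumscribing the object's bounding box with the object treated as unit
mass over its pixels. Zernike moments are implemented from the radial
polynomial definition (no installed package provides them).

Eccentricity, the aging marker, comes from the second-central-moment
ellipse: with λ_max ≥ λ_min the eigenvalues of the pixel covariance matrix,
`e = sqrt(1 − λ_min/λ_max)`, equal to sqrt(1 − (b/a)²) of the equivalent
ellipse; 0 is a circle, →1 an elongated nucleus. Axis lengths use the
4·sqrt(λ) diameter convention. Orientation is the major-axis angle from the
x-axis in (−90°, 90°], with y increasing downward. Conventions for
degenerate objects: a single pixel has perimeter 1, axes 1 px, e = 0;
perfectly collinear pixels give e = 1 − 1e-9 (flagged). No feature is ever
NaN.

Per-sample summaries average per-image feature means over the sample's
images (fields of view are sampled randomly per animal, then averaged per
animal), and all downstream inference uses n = samples, never pooled nuclei.

## Per-cell marker intensity

Integrated density is the sum of marker-channel pixel values strictly above
a threshold, over the whole image; intensity per cell divides by the number
of nuclei segmented in the paired DAPI channel (never marker-channel
objects). The threshold is a high quantile (default 0.999) of a
negative-control image's pixels and is shared by every image of an
experiment; a per-object masked mode is intentionally not the default.
Random subsets of k fields of view per sample are drawn without replacement,
seed-deterministic. Per-sample means over the sampled images feed the group
statistics.

## Phenotype statistics

Features are z-scored per column ((x − mean)/SD, n−1 denominator;
zero-variance columns dropped with a warning) before PCA, because the 53
descriptors mix px, px² and dimensionless units. PCA is an SVD of the
centred matrix. Loadings are *recomputed as Pearson correlations* between
each original variable and each component score — that correlation, not the
eigenvector weight, defines a variable's contribution here (on z-scored
input the two agree up to the factor S_k/√(n−1), an equivalence the tests
check). Contributors are ranked by |loading|; each component's sign is fixed
so its strongest variable loads positively, making output deterministic.
Group structure on the PC1–PC2 plane is summarised by per-group centroids,
95% confidence ellipses (χ² quantile of the sample covariance), and the
silhouette coefficient as the scalar separation measure.

Two regressions connect the readouts, both at the sample level:

- age trend: OLS of a per-sample outcome (R, eccentricity, intensity) on the
  ordinal group code; slope, CI, p.
- marker model: OLS of per-sample marker intensity on age code and mean
  eccentricity, additive, no interaction. The "independent contribution" of
  a predictor is its partial R² = R²(full) − R²(other predictor alone), the
  last-added increment. Designs with |corr(age, eccentricity)| > 0.99 are
  refused as collinear.

PCA can be run on nuclei-level rows (for separation displays, the default)
or on the per-sample table (for inference); both are plain data-frame
inputs.

## Synthetic cohort generator

The generator emulates the statistical structure the analyses assume, with
every generated object recorded once in ground-truth tables so recovery
tests never read truth from pixels. Defaults describe a murine aging cohort:
three ordinal groups (young/middle/aged), 5 animals per group, 5 fields of
view per animal, 6–12 nuclei per field (30–60 per animal), 256×256 px
images.

*Surfaces.* Each sample's mask is a gentle random quartic baseline plus an
i.i.d. Gaussian per-column perturbation smoothed with a 5-column moving
average (tissue-scale undulation; the spatial frequency is a parameter since
it is not identified by the roughness statistic) and rescaled so the
expected mean |perturbation| equals the group's amplitude: 1 px (young),
2 px (middle), 4 px (aged). The truth table stores the realized mean
absolute perturbation. Masks are 8-bit PNG; the surface is exactly one
pixel per column.

*Nuclei.* Ellipses with semi-major axis uniform in 9.5–10.5 px, orientation
uniform, eccentricity Gaussian per nucleus around an animal-level mean;
placement is rejection-sampled so inflated radii plus a 4 px margin never
touch, isolating segmentation from the morphometry under test. Each nucleus
also carries a smooth boundary wobble (radial Fourier modes 3–6, 5%
amplitude, recorded in truth): real nuclei are not perfect ellipses, and
without the wobble the 53 descriptors are near-deterministic transforms of
a single latent axis ratio, which makes their PCA ranking degenerate.
Modes ≥ 3 leave the centroid and the moments ellipse essentially unchanged
(measured eccentricity bias < 0.001).

*Effect sizes.* Eccentricity means are 0.57 / 0.67 / 0.77 for
young/middle/aged with within-animal SD 0.06 and between-animal SD 0.025.
The between-animal term reflects real biological variability and keeps the
age-code/eccentricity design well conditioned at the sample level. The
young→aged shift (~3 pooled within-group SD) was calibrated once so that
young and aged nuclei form clearly segregated PCA clusters (silhouette
comfortably above 0.3) with eccentricity among the top-10 PC1 contributors —
the qualitative structure the pipeline is designed to detect; at a 2-SD
shift that segregation is marginal.

*Marker channel.* Per-nucleus integrated intensity is
intercept(group) + slope·e + noise with intercepts 800/650/500 a.u. (a
longevity marker falling with age), slope −300 a.u. per unit eccentricity,
and Gaussian noise SD 50. The intensity is spread evenly over the nucleus
pixels in a float32 TIFF (zero background), so programmed totals are exact;
DAPI images are 16-bit TIFF with Gaussian background and foreground noise.
A faint negative-control image accompanies each cohort for thresholding.

*What the generator does not emulate:* marker-channel autofluorescence
background, optical blur and shading, touching or overlapping nuclei,
histological stain colour, and segmentation errors beyond pixelation.
Passing tests therefore demonstrate correctness of the measurement and
statistics machinery under the stated cohort law, not robustness to the
full messiness of real microscopy.

## Determinism and problem sizes

One config seed fans out to per-sample and per-stage sub-streams via
spawned seed sequences, so a fixed seed gives a bit-identical cohort and an
identical end-to-end report, and any stage can be re-run in isolation.
Replicate studies (coefficient recovery over 200 cohorts, intensity
detection power over 100) run on the generator's ground-truth tables — the
same cohort law without rasterisation — while the pixel path is checked
exactly against the table path on a noise-free cohort; this keeps the full
suite under a minute. Cohort-scale image analyses use the default 15-sample,
75-image cohort.

## Known limitations

- The 53-descriptor roster is a declared convention (23 geometry + 30
  Zernike); other toolkits' feature sets differ in perimeter and Zernike
  conventions, so absolute values of perimeter-derived and Zernike features
  are comparable only within this package.
- The marker model is additive with two predictors; interactions and
  standardized coefficients are out of scope.
- `R` compares surfaces of similar lateral extent; masks whose tissue span
  differs grossly should be compared with care since quartic flexibility is
  fixed.
- Sample-level inference assumes per-sample averages are exchangeable;
  mixed-effects models are intentionally not provided (averaging within
  sample is the design).
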
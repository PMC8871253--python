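# Methods

`lvradiomics` implements, as a tested and reusable pipeline, a radiomics
analysis of the left-ventricle (LV) myocardium on cardiac-CT-like
grayscale images: per-ROI gray-level normalization, a 377-feature texture and
shape vector, feature screening, an eleven-member classifier zoo, an ensemble
machine-learning (EML) score, shadow-feature (Boruta-style) relevance
selection, and group-comparison statistics.  Because no patient images are
available, every stage is exercised on synthetic two-class cohorts whose
statistical structure emulates a hypertensive (HTN) versus normotensive
control (NC) study population.

## The synthetic cohort model

Each subject is generated from a latent "remodeling" variable
`u ~ N(0, 1)`:

- **Septum width** (mm) is `mean + sd·u`, truncated at 0 by redrawing `u`
  alone, with class parameters HTN `N(10.01, 2.7)` and NC `N(8.15, 1.66)` —
  the clinical calibration values for the emulated cohort.  Because geometry feasibility
  never redraws `u`, the septum marginal is exactly the truncated normal.
- **ROI geometry**: polygon area (pixels) and second-moment elongation are
  normal draws whose deviations correlate with `u` at `rho = 0.5`
  (HTN: area `N(3495, 1246)`, elongation `N(2.17, 0.82)`; NC:
  `N(2515, 736)` and `N(1.55, 0.48)` — the LV shape-feature scales of the
  emulated cohort).  Area is truncated to `[600, 0.33·size²]` and additionally to
  what fits inside the image for the drawn elongation; elongation to
  `[1.02, 5]`.
- **Texture**: the ROI interior carries a Gaussian random field — white
  noise smoothed with a Gaussian kernel of width `(corr_length − 1)/2` and
  rescaled to the class noise SD — on a base mean of 1200 gray levels
  (16-bit).  The per-subject correlation length is the class value scaled
  by `exp(0.15·u)`, so more "remodeled" subjects have longer-range spatial
  correlation.  Class values: HTN `corr_length 2.8, noise SD 130`; NC
  `2.0 / 110`.  A correlation length of 1 means white noise.
- **ROI shape**: a star-shaped 24-vertex polygon around a rotated ellipse
  with ±7 % smoothed radial jitter; star-shaped polygons are always simple.
- **Clinical covariates** are sampled from the study marginals (sex,
  age, BMI, diabetes, dyslipidemia per group); only septum width is coupled
  to the image phenotype — the other covariates are independent given the
  group, an acknowledged simplification.

The latent-variable coupling encodes the study premise that septum
thickening and myocardial texture change are two faces of one structural
process; it is what makes an image-derived score correlate with septum
width *within* groups and not merely between them.  No quantitative texture
effect size is reported anywhere for this contrast, so the coupling
constants (`rho = 0.5`, `kappa = 0.15`) and the class texture parameters
are the generator's own definition of a "moderate effect", fixed once.

What the generator deliberately does not model: 3-D anatomy, cardiac
phase, contrast kinetics, scanner noise spectra, segmentation variability,
or correlated clinical covariates.  Passing tests therefore demonstrate
that the *pipeline machinery* behaves correctly under a controlled,
plausible effect structure — not that clinical effect sizes are
recoverable from real CT.  In particular the synthetic effect is cleaner
than clinical data, so replicate ensemble AUCs run higher than one would
expect on patient cohorts; that is expected and not a claim about real
data.

## Normalization and quantization

ROI statistics use masked pixels only.  Gray levels are clipped to
`μ ± 3σ` (population SD) and mapped linearly to integer levels
`1..Ng`, upper edge closed; `σ = 0` maps everything to `⌈Ng/2⌉` with a
warning.  `Ng = 64` for co-occurrence and run-length features, `Ng = 256`
for histogram, gradient, autoregressive and wavelet features (the
convention of the classical texture-analysis software whose feature names
the manifest reproduces).  Normalization is affine-invariant, so the
quantized families are unchanged by linear gray-scale transformations.
Pixel centers sit at `(col + 0.5, row + 0.5)`; the inside test is even-odd.

## The feature manifest (377 = 9 + 5 + 220 + 20 + 5 + 20 + 98)

- **Histogram (9)**: mean, population variance, skewness, excess kurtosis
  (0 for constant ROIs), nearest-rank percentiles 1/10/50/90/99.
- **Gradient (5)**: central-difference magnitude statistics on interior
  pixels (all four 4-neighbors in-mask); `GrNonZeros` is the fraction with
  non-zero gradient.
- **Co-occurrence (220)**: 11 Haralick-family statistics × 20 offsets
  `(d,0), (0,d), (d,d), (d,−d)` for `d = 1..5`; symmetric accumulation;
  pairs crossing the mask are discarded; natural-log entropies with
  `0·ln 0 = 0`; `Correlat` defined as 0 for degenerate marginals.
- **Run-length (20)**: 5 statistics × 4 directions; runs truncated at the
  mask boundary and at scan-line ends.
- **Autoregressive (5)**: first-order causal model (left, upper-left,
  upper, upper-right) fit by least squares on mean-centered levels;
  minimum support 20 pixels, otherwise missing; `Sigma` is the residual SD.
- **Wavelet (20)**: Haar subband energies at dyadic scales 1–5, computed by
  an explicit 2×2 block pyramid; a coefficient contributes only when its
  full spatial support lies inside the mask, so energies are
  background-free.  `LH` is high-pass along rows (responds to horizontal
  stripes).  Scales without a fully supported block are missing.
- **Geometry (98)**: intensity-independent descriptors of the binary mask
  (area, perimeter, convexity, moment ellipse, Feret extents at 16 angles
  raw and area-normalized, Hu invariants, central/normalized moments to
  order 4, radial-distance and projection-profile statistics).  The
  original software's geometry definitions are unpublished; these are
  documented reconstructions carrying the same names (`GeoF`, `GeoEl`,
  `GeoW12`, …), versioned as `manifest_v1`, and no numeric agreement with
  values from the original extractor is claimed.  `GeoEl` uses unit-square pixel
  moments (each pixel adds 1/12 to both axis variances) so a `w × h`
  rectangle yields exactly `max(w,h)/min(w,h)`.

Features undefined for a ROI are recorded as NaN and handled by screening.

## Screening, scaling, split

Features are screened on the training portion only, in order: any missing
value; > 90 % identical values; absolute Pearson correlation with the
binary label below 1e-5 or above 0.95.  Autoscaling subtracts the train
mean and divides by the train *sample* SD (ddof = 1); test data always use
train statistics.  The cohort splits 70:30 (nearest-count rounding,
stratified by class).

## Classifier zoo and the EML score

Eleven model families map to standard implementations (PLS-DA, Gaussian
naive Bayes, unpenalized binomial GLM, ridge logistic regression, linear
large-margin classifier, 2-hidden-layer feed-forward network, decision
tree, random forest, gradient-boosted trees, 1-hidden-layer network, RBF
SVM).  Per-model confidence is the predicted-class probability where
available, otherwise the absolute decision margin through a logistic map.
Cross-validation accuracy comes from stratified k-fold (default 10) on
the training set; optional small per-model grids tune hyperparameters.

Models with accuracy **strictly** above 0.60 vote; the gate and the vote
weight default to cross-validation accuracy (the alternative, test
accuracy, is exposed — the choice between the two is genuinely ambiguous
and the default is flagged as such).  The per-sample score is
`Σ_m sign_m · acc_m · conf_m` with sign +1 for an HTN call, −1 for NC.
The operating cutoff maximizes Youden's J over midpoints of adjacent
sorted unique scores (±∞ included), ties broken toward higher
specificity; it is computed on the test samples, as are the group score
summaries.  AUC is the Mann–Whitney statistic with a DeLong
structural-component SE and a one-sample normal p-value against 0.5.
The score is correlated (Pearson) with test-set septum width.

In null-cohort studies the gate is set to 0 so that every model votes:
under the null, CV accuracies hover near 0.5 and the strict gate would
correctly abort with "no model selected", but the quantity of interest —
the ensemble score's chance-level AUC — needs votes to exist.

## Shadow-feature relevance selection

Per iteration: every feature column is independently permuted to build a
shadow table; a random forest (entropy criterion, 100 trees by default)
is trained on the combined table; a feature hits when its mean
impurity-decrease importance strictly exceeds the maximum shadow
importance.  The canonical procedure runs on the order of 2000
iterations; pipeline and test defaults are smaller (200 and below) purely
as a problem-size choice, with the iteration count exposed.  There is no
single canonical rule for aggregating iterations into a final feature
list; the default rule
confirms a feature when its hit count is significantly above the
`Binomial(n_iter, ½)` reference (one-sided at α/2 = 0.005, Bonferroni over
features), the canonical choice; a plain hit-fraction > ½ rule is
available.  There is no three-state "tentative" decision.

## Group statistics and the smile table

Pooled-variance Student t per feature (Welch optional), Benjamini–Hochberg
FDR, Yates-corrected χ² for 2×2 tables (the continuity correction
reproduces the emulated cohort table's p-values, 0.038 for sex and 0.006
for diabetes; the uncorrected statistic gives smaller ones), and the D'Agostino–Pearson omnibus normality test
(reported alongside, but deliberately not used to gate the t-tests).  Fold change is `mean_HTN / mean_NC` on the raw feature scale —
autoscaled columns have mean 0 and no meaningful ratio — with the "±2"
threshold read two-sidedly (FC ≥ 2 or ≤ ½); non-positive class means mark
FC undefined.  The smile coordinates are `log2 FC` against `−log10` of the
FDR-adjusted p.

## Numerical and design choices

- Natural log for texture entropies, log2 for fold change, log10 for the
  smile ordinate.
- Degenerate inputs: empty masks and single-class label vectors raise;
  constant ROIs produce defined values (mid-level mapping, zero skewness);
  features that cannot be computed are NaN, never silently zero.
- Determinism: one integer seed drives cohort generation, splitting,
  every stochastic model, and the shadow permutations; two runs with the
  same configuration produce byte-identical summary JSON.
- Problem sizes in the test and acceptance runs (20 ensemble replicates at
  n = 158, 200-iteration / 50-tree shadow runs, 5-fold CV in replicate
  studies) are scaled-down study sizes chosen so the full suite runs on a
  single CPU in minutes; all are configurable upward.

## Known limitations

- The geometry-descriptor reconstructions and the exact quantization
  depths are conventions, not a bit-level replication of the original
  closed-source feature extractor.
- The clinical cohort this analysis emulates is not publicly deposited,
  so its headline numbers (ensemble accuracy 0.70, AUC 0.731, cutoff
  31.98, R² = 0.5292, 43 fold-change-flagged and 23 shadow-confirmed
  features) are not reproducible from synthetic data, and this package
  does not claim to reproduce them.  The pipeline's
  correctness is instead established by brute-force oracle equivalence,
  hand-computed examples, and calibrated/null simulation properties.
- EML score magnitudes depend on the number of gated models, so cutoffs
  are comparable only within one configuration.
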
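# Methods

`neurodiff` detects neuronal differentiation in live PC12-like cell
populations from label-free phase-contrast micrographs. The core idea is
population-level: instead of tracing individual neurites, the pipeline
summarizes every image by a fixed vector of morphometric features and lets a
linear classifier learn which combination distinguishes a differentiating
culture (NGF-stimulated) from a proliferating one (untreated control). This
note documents the model, its assumptions, the tunable parameters, the
synthetic study-condition generator, and the numerical choices made where
the design was genuinely open.

## Pipeline overview

1. **Calibration** (`neurodiff.calibration`) — empty collagen-coated wells
   imaged over several days yield two thresholds: the range-filter threshold
   `t_r` for outlier detection and the strong edge threshold `t_e` for ROI
   detection, plus the choice of edge-detector variant.
2. **Feature extraction** (`neurodiff.features`) — outlier filtering, ROI
   segmentation (median filter → edge detection → morphological closing →
   artifact removal) and 32 per-image features, variance-stabilized.
3. **Screening** (`neurodiff.screening`) — features that inherit the
   scan-order autocorrelation of the illumination are removed by a
   Breusch–Godfrey test; the `k` least-autocorrelated features remain.
4. **Classification** (`neurodiff.classify`) — nested, stratified
   cross-validation trains an ensemble of five Fisher linear discriminants
   with a stepwise-selected feature set, a data-chosen training day, and
   per-member thresholds at the sensitivity = specificity point.
5. **Population statistics** (`neurodiff.stats`) — proliferation kinetics,
   sensitivity/specificity with exact binomial intervals, effect-size-based
   sample-size planning, and the mapping of classifier scores onto the
   classical neurite-length criterion.

## Calibration

The intensity-spread feature of an image is the width of the central `q`
probability mass of its pixel intensities (default `q` = 0.68, i.e. the
aq68 feature). `t_r` is the per-well mean of this spread over all
calibration images, taking the **larger** of the well means — the
conservative choice that suppresses background fluctuation more robustly.
`t_r` lives on the raw intensity scale of the acquisition (a.u. of the
bit depth).

The edge threshold is defined operationally: for a given detector, `t_e` is
the response-magnitude quantile that marks a fraction `roi_fraction`
(default 0.05) of the image's pixels. Candidates are four Canny variants
(weak threshold at 0.025, 0.05, 0.10 or 0.20 of the strong threshold — the
0.05 variant is listed first and is the preferred tie-break) and the
Prewitt, Sobel, Roberts and Laplacian-of-Gaussian operators. Per candidate,
per-image thresholds are tabulated against well and day; a two-way ANOVA
(well, day, interaction) quantifies the factor influence, and standardized
pairwise mean differences (Cohen's-d scaling: absolute mean difference over
the pooled standard deviation) summarize between-well versus within-well
across-day variability. The candidate with the smallest within-well
across-day standardized difference is selected; `t_e` is again the larger
per-well mean, on intensities normalized to [0, 1] by bit depth — so the
two calibrated thresholds deliberately live on different scales, and the
profile records both. Because the four Canny variants share the
strong-threshold statistics (they differ only in their weak threshold,
which acts downstream in the hysteresis), selection among them reduces to
the configured preference order; the plain detectors compete on equal
terms.

## Feature extraction

**Outlier filter.** A range filter counts pixels whose local max − min over
an `l_r` × `l_r` neighbourhood (default 3 × 3) exceeds `t_r`. An image is
rejected when the count is at most one cell area (empty/underexposed), at
least the image area minus one cell area (overexposed), or when the
segmentation finds no segment. The one-cell area is derived from the lower
bound of the cell radius `r_c` (default 32 px ≈ 2.5 µm at 0.078 µm/px).
Outliers are flagged in the feature table, never silently dropped.

**Segmentation.** Median filter (`l_m` = 3) → edge detection with the
calibrated detector (for Canny, hysteresis with strong `t_e` and weak
`weak_fraction · t_e`; for the others, response magnitude ≥ `t_e`) →
morphological closing with a discrete disk of radius 6.5 px (diameter
13 px, the length scale of a neurite) → removal of components smaller than
`t_a` = 50 px → 8-connected labelling. 8-connectivity everywhere (including
the Euler number) because neurites are thin, often diagonal structures.

**Features.** 12 global statistics of the intensity distribution (mean
absolute deviation, mean, median, SD, median absolute deviation from the
median, total and local entropy summaries, interquartile range and the
central 68 %/95 % quantile widths), 10 ROI-level quantities (ROI area,
union of per-segment convex hulls, skeleton length, skeleton branch and
endpoints, endpoints of the thinned ROI, Euler number, summed convex-hull
area `caSum`, summed filled area `faSum`, segment count) and mean/SD over
segments of 5 shape descriptors (solidity as filled/convex area, convex and
filled area relative to segment size, eccentricity of the fitted ellipse,
extent as filled area over bounding-box area). Areas are reported in
percent of the image (hulls may overlap, so `caSum` can exceed 100 %);
intensities in percent of the maximal representable intensity. Local
entropy uses a 9 × 9 window on intensities collapsed to 64 bins, base-2
logarithm (configurable; no canonical convention exists).

**Variance stabilization.** Features bounded by the pixel total
(`segment`, `segmentConv`, `faSum` — `caSum` is excluded because it is
unbounded) are treated as binomial counts x of N and transformed to
arcsin √((x + 3/8)/(N + 3/4)), the Anscombe rule. Unbounded count-, area-
and intensity-like features get the square root, which maps a Poisson
variance to ≈ 1/4 independent of the mean. Entropy features are left
unchanged by default (a log option exists); the Euler number (signed) and
the unit-free shape summaries are not transformed. Transform state is
tracked and double application is an error.

## Autocorrelation screening

Radial vignetting plus line-wise scanning of wells makes consecutive images
correlated; features tracking illumination inherit that structure. Per
feature and per (condition, well) series — ordered by day, then scan index
— an intercept-only regression's residuals are tested for AR(p)
autocorrelation (Breusch–Godfrey: auxiliary regression of residuals on an
intercept and p lagged residuals with pre-sample zeros; statistic n·R²,
chi-square with p degrees of freedom). Defaults: p = 1; evidence is
aggregated per feature as the **median** statistic across series (robust to
one anomalous condition), and the k = 20 least-autocorrelated of the 32
features are kept. The screening never reads class labels, so it cannot
leak the differentiation signal into model selection. The report always
records the full ranking so any k can be revisited.

## Classification

**Discriminant.** Fisher's linear discriminant: w ∝ S_w⁻¹(μ₁ − μ₀) with the
pooled within-class scatter S_w (pseudo-inverse when singular), offset so
that the projected class-mean midpoint scores zero.

**Cross-validation layout.** 10 stratified folds (balanced over condition
and day, deterministic given the seed). Feature search: for each
leave-one-fold-out repetition, a greedy forward/backward search adds or
removes one feature at a time, scoring candidate sets by a 5-fold inner-CV
correctness rate (unweighted accuracy at the midpoint cut) and stopping
when the best move improves it by less than `stop_epsilon` = 0.01; the
repetition's set is then judged by the Gini index (2·AUC − 1, ties counted
half) on the held-out fold pooled over **all** days, and the best set
across repetitions wins (ties: fewer features, then lexicographic order).
The training day is then the day whose day-restricted training generalizes
best: leave-one-fold-out training on that day's images, Gini on the
held-out fold over all days, largest mean wins, ties to the earliest day.

**Ensemble.** The 10 folds form 5 disjoint consecutive pairs; member i is
trained only on pair i restricted to the training day, so the five members
are statistically independent and each sees a realistically small sample.
Member thresholds θᵢ are calibrated on the remaining eight folds (all
days) at the point where sensitivity equals specificity (linear
interpolation between ROC steps guarantees |sens − spec| ≤ 1/min(n₁, n₀));
the dispersion is the standard deviation of the member's scores on those
same folds (a MAD option exists). Scores are standardized per member,
zᵢ = (sᵢ − θᵢ)/dispersionᵢ, and an image's verdict is the median z over
members: strictly positive means differentiated (z = 0 is classified
undifferentiated). Fold provenance is stored in the model so that held-out
evaluation can be reconstructed after reloading.

## Population statistics

* **Proliferation**: ordinary least squares of logit(`faSum` as a fraction)
  on day; the slope is the per-day log-odds growth of confluency. Exact 0/1
  fractions are clipped (configurable ε, warned).
* **Performance**: sensitivity = P(z > θ | differentiated), specificity =
  P(z ≤ θ | undifferentiated), with Clopper–Pearson intervals (the exact
  method is a deliberate, conservative default).
* **Sample size**: treating the mean standardized score as normal, the
  images needed to distinguish it from the decision boundary at one-sided
  level α (default 0.05) and power 1 − β (default 0.90) are
  n = ⌈((z₁₋α + z_power)/ES)²⌉ with effect size ES = mean(z)/sd(z). The
  scaling law n(ES/c) = c²·n(ES) holds exactly; halving the effect size
  quadruples the requirement.
* **Correspondence**: the classical criterion calls a cell differentiated
  when its longest neurite exceeds ρ cell diameters (default ρ = 1). Per
  image, m is the mean ratio over measured cells; the package reports the
  Pearson correlation between z and m (Fisher-transform CI) and an OLS line
  of z on (m − ρ), whose intercept is the classifier threshold equivalent
  to the biological criterion.
* **Apoptosis**: specific DNA fragmentation =
  (experimental % − spontaneous %)/(100 − spontaneous %) × 100.

## Synthetic study conditions

The generator (`neurodiff.synthetic`) emulates the structure the pipeline
must cope with, not photorealistic cells:

* **Technical artifacts** — multiplicative radial vignetting (default
  amplitude 0.10), a sinusoidal mean-intensity drift advancing one phase
  step per image in scan order (amplitude 0.05, period 10 images), and
  Gaussian sensor noise (SD 15 a.u. on the 12-bit scale, ≈ 0.4 % of the
  dynamic range). Manifest order is scan order, which is what the
  screening stage must detect.
* **Empty calibration wells** additionally carry a correlated substrate
  texture (amplitude 0.08, correlation length 2.5 px) emulating the
  in-focus collagen coating; this places the calibrated edge threshold
  above the sensor-noise floor of later cell images, where the cells, not
  the coating, dominate the focal plane.
* **Colonies** are soft-edged ellipses with a dark body (0.82 × background)
  and a bright phase halo (1.35 ×); the ROI operators respond to this local
  contrast, not to its polarity. Per image, colony radii are set so the
  covered-area fraction follows a logistic growth curve: logit(coverage) =
  logit(p₀) + growth_rate · day + jitter (SD 0.15). Default growth rates
  are 0.382/day for the control and 0.358/day for the differentiating
  condition — the reference proliferation kinetics the downstream
  regression must recover. Colony centres keep a minimum boundary gap
  (20 px at day 1) that shrinks exponentially with `clumping_rate`
  (default 0.10/day), so colonies stay disconnected early and increasingly
  touch and merge late — the crowding that erodes late-day detection.
* **Neurites** are anti-aliased quadratic-Bézier bridges (default width
  3 px, bright like the halo) connecting a colony to its nearest neighbour
  with probability `neurite_probability` (default 0.95 for NGF), modulated
  by a per-day profile (0.55, 0.75, 1.0, 1.0, …) that emulates
  differentiation setting in progressively and saturating at day 4.
  Discrimination therefore rests on how growth areas are physically
  connected, which is exactly what the shape features measure.
* **Abstract feature tables** (`generate_feature_table`,
  `generate_day_effect_table`) provide controlled effect sizes for
  classifier unit tests, including a day-resolved construction whose
  separability peaks at a designed day (large effect at day 4, weak start,
  eroded tail) for testing training-day selection. On rendered images the
  early-day separation is essentially perfect, which makes the rank-based
  day criterion tie across days; the abstract construction keeps the
  per-day effect graded so the peak is identifiable.

What passing tests on these conditions show — and what they do not: the
pipeline end-to-end recovers designed growth kinetics, separates the
designed phenotypes, and degrades under designed crowding; none of this
certifies performance on real micrographs, whose texture, debris,
focus drift and phenotype variability the generator does not attempt to
model.

## Problem sizes and numerical choices

* The end-to-end evaluation uses a 2-condition × 6-day study with 60
  images per condition and day at 256 × 256 px, plus a 30-image-per-
  condition-day external set with clumping rate 0.5; these sizes give
  stable per-day Gini estimates while keeping a full run in minutes on a
  single core.
* Unit-test fixtures use 128 px images with 5 colonies of radius 8 px and
  a cell-radius parameter scaled accordingly (`r_c` = 8–16 px).
* Quantiles are linear-interpolation sample quantiles; the per-segment
  summary SD uses the population convention (a single segment has SD 0);
  empty segmentations report 0 for ROI features with `segment_valid`
  False so tables stay rectangular and classifiers can exclude such rows.
* Tie-breaks are deterministic everywhere: detector candidates by list
  order, feature sets by size then name, training days by earliest day.
* The degenerate constant image yields an empty segmentation (not an
  error); constant series make the autocorrelation test degenerate and are
  excluded from screening aggregation.

## Known limitations

* The four Canny weak-threshold variants cannot be distinguished by the
  strong-threshold stability criterion as implemented; their ordering in
  the candidate list decides ties.
* The stepwise search is greedy and can return a local optimum; the nested
  layout only guards against overfitting, not against path dependence.
* Sample-size planning assumes normally distributed standardized scores;
  heavy-tailed score distributions will make it optimistic.
* The synthetic generator's phenotype difference is purely geometric
  (bridges); real differentiation also changes cell-body texture, which
  the feature set could exploit but the tests cannot certify.
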
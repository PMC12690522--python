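# Methods note

This note records the model implemented by `ifquant`, the parameter
defaults and their rationale, what the synthetic generator does and does
not emulate, the numerical conventions the implementation commits to, and
the problem sizes used for validation.

## Analysis model

### Segmentation

The nuclear channel of a maximum-intensity projection is turned into a
pseudo-probability map: Gaussian smoothing with σ = `smoothing_scale /
pixel_size` pixels (default scale 0.5 µm, roughly one diffraction-limited
PSF radius at 40×), followed by a robust rescale that maps the 0.1st and
99.9th intensity percentiles to 0 and 1 and clips. This stands in for the
per-pixel foreground probability a trained pixel classifier would output;
any array in [0, 1] can be substituted at the same interface. A constant
map raises `DegenerateImageError` rather than producing a silent empty
mask.

The map is binarized with Otsu's method: intensities are binned into a
256-bin histogram over the observed range and the threshold maximizes the
between-class variance σ²_b(t) = w₀(t)·w₁(t)·(µ₀(t) − µ₁(t))². Pixels
strictly above the threshold (the center of the argmax bin) are
foreground. Touching nuclei are split by a watershed on the negated
Euclidean distance transform, seeded at local maxima of the distance
transform that are at least `min_seed_distance` apart (default 2.5 µm —
just under the diameter of the smallest admissible 5 µm² nucleus, so a
single small nucleus cannot be over-seeded while pairs of median-sized
nuclei still get two seeds). Foreground components are 4-connected; seed
maxima use 8-connectivity. Components left without any seed (smaller than
the seed spacing) are kept as single objects. Labels are relabeled to
consecutive 1..n.

### Per-object measurement and size gating

Object area is pixel count × `pixel_size`². The default pixel size,
0.1625 µm, is a 6.5 µm camera pixel behind a 40× objective; the validation
scale 0.325 µm/px corresponds to the same sensor with 2×2 binning. Mean
raw intensity is computed per channel over the object's pixels. Objects
with area outside [5, 60] µm² — both bounds **inclusive**, checked with
plain `<=` on the float areas — are discarded as debris or clumps, and the
dropped count is logged and reported.

Background is deliberately *not* subtracted before measurement; the
normalization step below absorbs additive background together with
multiplicative gain into the per-image baseline, which is why cutoffs are
transferable across images.

### Baseline normalization

Per image and per channel, the size-filtered nuclei are ranked by that
channel's raw mean, and the baseline is the mean over the lowest
⌈0.1·n⌉ nuclei (floor 1; `DegenerateBaselineError` if the baseline is
non-positive). Ranking is done independently per channel: a cell dim in
Sox10 need not be dim in tdTomato, and the baseline is meant to estimate
each channel's own negative-cell level. Normalized intensity is
raw / baseline, a unitless ratio invariant to per-image exposure and gain.
The implicit assumption is that ≥10% of cells in every image are negative
for each marker; fields of uniformly positive cells violate it and would
need an external baseline.

### Classification and aggregation

A marker call compares the normalized intensity to a fixed cutoff shared
by all images. The default rule is **strict** (`>`), matching the
binarization convention; an **inclusive** rule (`≥`) is available for
stratifications where boundary cells must land in exactly one class.
Presets: `lineage_high` (Sox10 > 2.5, tdTomato > 3) for high-stringency
lineage scoring, `tracer_pair2` (both > 2) for tracer/identity panels, and
`uniform2` (five markers > 2) for broader proportion panels. Conjunctions
are pixel-free logical ANDs of per-cell calls, so any conjunction fraction
is bounded above by each of its member fractions.

Proportions are computed per image; per-sample values are **unweighted
means over that sample's images** (not pooled counts, so a crowded image
does not dominate its sample); per-genotype summaries average the sample
means. Images with zero size-filtered nuclei are flagged in the manifest
warnings and excluded from the averages rather than contributing 0/0.

## Cohort statistics

* **Kaplan–Meier**: product-limit estimator on right-censored tables.
  Median survival is the earliest observed time with S(t) ≤ 0.5 and is
  `None` when the curve never reaches 0.5 (reported as undefined, never as
  the largest time).
* **Mann–Whitney U** (two-sided, unpaired): midranks for ties. When the
  pooled sample size is ≤ 12 and there are no ties, the exact null
  distribution of U is built by the standard counting recurrence and
  p = min(1, 2·min(tail probabilities)). Otherwise the normal
  approximation is used with tie-corrected variance and a 0.5 continuity
  correction. Ties force the approximate route even for small samples,
  because the tie-free exact distribution would be wrong.
* **Growth alignment**: each animal's measurement days are shifted by its
  induction day and snapped to fixed bins (default width 1 day); per
  group and bin the summary is mean and SD, with SD reported as NaN for
  n < 2 instead of 0. Animals without a recorded induction day are
  excluded and reported. Sizes are summarized as measured; an optional
  normalization to each animal's day-0 size exists but is off by default,
  since absolute sizes are the quantity of interest and per-animal
  rescaling changes the null hypothesis of the downstream rank test.
* **Box summaries**: median and quartiles by linear interpolation
  (`numpy` default), matching the convention of mainstream plotting
  software.

## Synthetic generator: what it emulates, and what it does not

Scenes are rendered on a 16-bit sensor grid (default 2304×2304 at
0.1625 µm/px). Nuclei are axis-aligned ellipses with axis ratio
U(0.75, 1) and area U(5, 60) µm² — the admissible size range itself, so
the size filter acts only on clipped or merged objects. Centroids are
placed by hard-core rejection sampling with a minimum edge gap of 1.5 µm;
a configurable fraction of cells (default 10%) is placed as deliberately
touching pairs at 0.9× the sum of equivalent radii to exercise the
watershed. Placement failure after `max_place_attempts` raises
`SceneOvercrowdedError` rather than silently under-filling.

Each cell is assigned a compartment (tumor, i.e. tracer-lineage, vs
stroma, default 40% tumor) and per-marker Bernoulli states with
compartment-specific positive fractions (defaults: Sox10 0.95/0.02,
tdTomato 1.0/0.0). Intensities are lognormal, parameterized by the
**median** (so the headline levels survive any dispersion setting):
positive median 8000 counts, negative 400, dispersion σ = 0.3; nuclear
channel median 15000, σ = 0.15. The rendered signal is
gain × signal + background (default 300 counts) + Gaussian read noise
(SD 50), clipped to [0, 65535]; the clipped-pixel fraction per channel is
reported so saturation is never silent. Survival times are exponential
(scale = median/ln 2) with uniform-fraction censoring at T·U(0, 1);
growth is exponential with Gaussian measurement noise.

Not emulated: chromatin texture, the microscope PSF and channel crosstalk,
z-stack structure (scenes are born as projections), spatial clustering of
compartments, autofluorescence gradients, and staining-batch effects. The
stromal marker fractions are plausibility settings, not calibrated
measurements. Consequently the generator validates the *pipeline's
arithmetic and its invariances* (recovery of known fractions, gain
invariance, segmentation of known geometry), not biological effect sizes.
Generator defaults were fixed from the acquisition description first and
never tuned to make validations pass.

## Numerical conventions

* All randomness flows from `numpy.random.default_rng(SeedSequence(seed))`;
  derived sub-seeds are drawn as integers below 2³¹.
* **Otsu tie canonicalization**: only cut points immediately following a
  non-empty histogram bin are candidates. Cuts after empty bins produce
  the *identical* partition as the last non-empty cut, and which of the
  duplicates wins the argmax would otherwise depend on float summation
  order — the one observed source of disagreement between independent
  implementations. Both the production code and the exhaustive oracle
  apply the same rule.
* CSV exports use `float_format="%.6g"`. Six significant digits are far
  beyond biological meaning here, and make the gain-invariance guarantee
  byte-exact: ratios after a 0.5× or 2× gain change are ulp-identical, and
  a 10× change perturbs ratios by at most a few ulp, far below the
  rounding quantum.
* Exact Mann–Whitney p-values are 2·min(tail) capped at 1; KM median uses
  the inf{t : S ≤ 0.5} convention; SD of a single observation is NaN.
* Label images use 4-connectivity for components and 8-connectivity for
  distance-transform maxima, the usual pairing that prevents diagonal
  leakage while keeping ridge maxima connected.

## Validation problem sizes

Chosen by this package as its own demonstration scale (small enough for a
CI budget, large enough for stable statistics):

* Unit scenes: 512–1024 px square at 0.325 µm/px, 120–500 cells.
* End-to-end recovery: 3 genotypes (tumor fractions 0.40/0.50/0.30) × 3
  samples × 5 images of 1024² px with 500 cells each — 45 images,
  ~22,000 cells; recovered tracer⁺ and Sox10⁺-within-tracer⁺ fractions are
  compared to the realized truth per genotype.
* Otsu: 200 random beta-mixture maps vs an exhaustive scan.
  Watershed: 100 constructed touching pairs (disk radii 2.0–4.3 µm at
  0.9× center spacing).
* Mann–Whitney: full enumeration for all rank patterns with pooled n ≤ 10,
  plus a 2000-replicate type-I-error simulation at n = 50 per arm.
* Kaplan–Meier: a hand-computed censored table, 100 censor-free tables
  against the empirical survival function, and median recovery at n = 10⁴
  for true medians 22/32/161 days.

## Known limitations

Watershed over-splits elongated nuclei whose long axis exceeds the seed
spacing; the probability-map stand-in has no learned texture model, so
real tissue needs a pixel classifier upstream; the baseline requires a
negative subpopulation per image; the exact rank test is limited to small
tie-free samples by design; and survival/growth generators are
single-parameter families intended for estimator validation, not disease
modeling.
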
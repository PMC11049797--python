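# Methods

## The measurement model

A photographed bee abdomen, lit to use the camera's dynamic range and
oriented with the long axis along image x, is reduced to a one-dimensional
brightness signal.  The three color channels are averaged with equal
weights and normalized by the bit-depth maximum (`2^8 − 1` or `2^16 − 1`).
Normalizing by the sensor maximum rather than the per-image maximum is
deliberate: the saturation cutoff (below) only has a fixed meaning on an
absolute scale, and per-image normalization would make specimens
incomparable across frames.

Two pixel classes are excluded before any statistic is computed: saturated
pixels, normalized value **strictly above 0.95** (specular highlights on
the cuticle), and desaturated pixels, value **exactly 0** (dead background
or underexposure).  Exclusion is implemented as masking — the pixels do not
participate in the medians — never as zero-filling, which would drag
profiles toward dark.  The boundary is asymmetric on purpose: 0.95 itself
is kept ("above 0.95" is strict), while desaturation is exact equality.

Each pixel column is collapsed to the **median** of its unmasked values.
The median, not the mean, makes the profile immune to moderate highlight
contamination: with up to ~20 % of pixels saturated at random, the column
median moves by well under half a percent (verified in the test suite).
Even-sized samples take the mean of the two middle values.  A column whose
pixels are all masked becomes a missing entry.

Abdomens differ in pixel length, so profiles are equalized to a common
length *L* before comparison: interior missing entries are filled by linear
interpolation between their nearest valid neighbours (edge gaps take the
nearest value), then the complete profile is resampled to *L* points by
linear interpolation over normalized position `[0, 1]`.  Linear
interpolation is the minimal order-preserving choice and leaves a complete
profile already at length *L* bit-identical.  The default `L = 1998` is a
dataset property (the longest abdomen observed at 8× magnification), not a
constant of nature; the tool exposes it.  Specimens with more than 50 % of
columns fully masked are rejected with an error (a saturation disaster, not
a fixable gap); below that, filled columns produce a warning with a count.
Interpolation over normalized position rather than raw index was an open
choice; normalized position treats the abdomen as the unit of length, which
is what equalization is for.

## Coloration index

The index is the trapezoidal area under the profile, with the **position
axis as vector index at unit spacing**:

    CI = Σ_{i=0}^{L-2} (v_i + v_{i+1}) / 2  ≈  mean gray × (L − 1)

Unit spacing (rather than a normalized [0, 1] axis) sets the index scale at
hundreds of units for L = 1998 — e.g. mean gray 0.22 gives CI ≈ 440 — which
keeps group differences visible at the integer level.  The index is always
computed on the length-equalized profile so that abdomen pixel length never
confounds brightness.  Higher index = lighter abdomen.  It is invariant to
profile reversal and linear in the profile values.

## Classification harness

Per colony of origin, profiles (raw, or UMAP-embedded) are evaluated with a
linear-kernel SVM over repeated stratified train/test splits (75 % train,
10 replicates by default).  Stratification is used because at ~50 samples
per class an unconstrained split can starve a class; each replicate draws
its seed from a named substream of the protocol seed, so the whole harness
is bit-reproducible.  Metrics are precision, recall, F1 and ROC AUC (from
the SVM decision scores, oriented toward the positive label — by default
the second class in sort order, i.e. 34 °C for temperature), summarized as
mean ± SD over replicates.  A `fixed_split` flag reuses the first split in
every replicate, for emulating protocols whose replicate SDs are zero.

UMAP preprocessing defaults to 75 neighbours / 2 components with
`min_dist = 0.1` and Euclidean metric (common defaults, exposed as
parameters), fitted once on the full per-colony dataset before splitting —
transductive, as in a preprocess-then-classify workflow.  Because this
leaks test-set geometry into the embedding, the leakage-free variant
(`umap_fit="train"`, backed by the sklearn-compatible `UmapLinearSVM`
estimator) refits UMAP inside each training split.  The parameter sweep
covers neighbours {5, 10, 20, 50, 75, 99} × dimensions 2–10 (54 cells).
The SVM regularization constant defaults to C = 1.0 (the common library
default; unknown for the original analysis) and is exposed.

## Inference chain

Group indices are checked with Shapiro–Wilk (per group and on pooled
residuals) and for variance homogeneity with pairwise two-sided F-ratio
tests, reporting the largest ratio and most extreme pairwise p (a single
Levene test is available as an alternative; which multi-group F procedure
the original analysis used is not derivable, so both are offered).  When
the residual Shapiro test rejects at α (default 0.05), the indices are
Box–Cox transformed (λ by profile maximum likelihood over the bounded
interval [−5, 5]; `(x^λ − 1)/λ`, log at λ = 0) before modelling.  The bound
is numerical, not statistical: for data far from 1, exponents beyond ±5
make the power transform collapse to a floating-point constant (all
contrast lost to cancellation), which silently zeroes every downstream
variance.  The transform is conditional and the condition is explicit and
configurable (`auto`/`always`/`never`).  The two-way ANOVA
(origin, temperature, interaction) uses Type II sums of squares: the design
is near-balanced (a specimen can be lost to saturation), Type II is
invariant to factor order and coincides with Type I under exact balance.
Tukey HSD runs on the same (possibly transformed) scale as the ANOVA over
all six pairwise contrasts of the four groups, for internal consistency.

## Synthetic data generator

The generator emulates what the pipeline actually responds to in a real
stereo-microscope frame: a dark cuticle field (`base_gray = 0.22`),
`n_tergites = 5` segments along x with darkened seams, brighter marks on
the anterior fraction (`yellow_band_fraction = 0.3`) of the first three
tergites, a configurable fraction of saturated specular pixels, and i.i.d.
Gaussian pixel noise, quantized to bit depth with R = G = B.  Images are
gray on purpose: the pipeline averages channels before anything else, so
hue cannot carry information through it, and "yellow" is modelled as
brightness.  Each image carries its ground truth — the quantized noise- and
highlight-free column brightness — which the extraction pipeline recovers
exactly on a clean image.

Group structure for the 2 × 2 design (defaults in parentheses):

* `origin_effect` (0.006 gray): extra brightness of the yellow colony's
  anterior marks, parameterized as the **mean-gray shift** it produces over
  the profile (per-pixel increment inside marks = effect / mark coverage);
  0.006 × 1997 ≈ 12 index units between colonies.
* `temperature_effect` (0.002 gray): global brightening at 34 °C, ≈ 4 index
  units — a deliberately weak (~0.2 within-group SD) signal.
* `specimen_sd` (0.01 gray): per-specimen global brightness jitter, the
  dominant source of within-group index variance (0.01 × 1997 ≈ 20 index
  units).  Pixel noise alone cannot produce realistic index SDs because the
  column medians average it away by roughly √height.
* `n_per_group` (50): 200 specimens in groups 30gray/34gray/30yellow/34yellow.

Abdomen widths are drawn uniformly from [0.75 L, L] so the equalization
path is always exercised.  A direct-profile fast path
(`generate_profiles`) skips rasterization for simulation-heavy statistics,
with per-column noise (`noise_sd = 0.005`) standing in for what pixel noise
leaves after the medians.

What the generator does **not** emulate: real tergite curvature and
vignetting, hue, patriline (genetic) substructure within colonies,
illumination drift between sessions, and focus gradients.  Passing tests
therefore demonstrate that the *computation* is correct and that the
analysis chain behaves as designed under known effects — not that the
biological effect sizes in any real colony match the defaults.

## Numerical and design choices

* Medians of even-sized samples: mean of the two middle values everywhere
  (including the brute-force test oracles).
* Rounding to bit depth uses round-half-to-even (numpy), which matters only
  for exact-tie gray levels.
* One ROI per image; duplicate ROI rows are an error, not a merge.
* Coordinates are 0-based half-open; profile length is exactly `x1 − x0`.
* All randomness flows from one master seed through `SeedSequence`
  substreams (simulation, UMAP, splits); two runs with equal seeds produce
  byte-identical output files.
* Simulation-based tests run at reduced problem sizes (profile lengths
  120–300 instead of 1998, replicate counts 1–2 instead of 10) chosen so
  the tested property, not the scale, dominates; the structural-replication
  and type-I-error checks keep the study-scale n = 50/group and L = 1998.

## Known limitations

* The 0.95/0.0 masking thresholds assume absolute-scale normalization; data
  already stretched per-image will mask the wrong pixels.
* Transductive UMAP (the default, matching the original workflow) slightly
  optimistic-biases classifier metrics; use `umap_fit="train"` for honest
  generalization estimates.
* The F-ratio variance check is sensitive to non-normality; prefer
  `method="levene"` for heavy-tailed indices.
* The coloration index collapses the entire profile; two abdomens with
  different band patterns but equal mean brightness get equal indices.
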
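# Methods

This note documents the statistical model behind `canedisc`, the defaults
and why they were chosen, the numerical conventions, and what the synthetic
data can and cannot say about real leaves.

## Pair classes and combinatorics

A trial is a families × blocks grid with at most one plot per cell and one
clone per plot; `leaves_per_plot` "+1" leaves are sampled per plot. Pairs of
leaf samples are unordered (canonicalised by sample id) and classified C1
(same plot ⇒ same individual), C2 (same family, different block) or C3
(different families). For F families present in all B blocks with L leaves,

* |C1| = F · B · C(L, 2),
* |C2| = F · C(B, 2) · L²,
* |C3| = C(F·B·L, 2) − |C1| − |C2|.

The dual-block analysis subset (7 families × 2 blocks × 3 leaves) therefore
gives 861 pairs: 42 C1, 63 C2, 756 C3. Families present in only one block
are supported; the dual-block subset is a filter, not a separate design.

## Image attributes

Images are 8-bit RGB; segmentation assumes a bright background plane: a
pixel is background when its minimum channel exceeds a brightness threshold
(default 240), and only the largest 8-connected foreground component is
kept. Attributes of an image are the per-channel mean intensities over the
leaf mask. The mean (rather than median or histogram) is the minimal
summary consistent with treating each band as one variable; it is also the
statistic whose bootstrap behaviour the Mahalanobis protocol needs.

Pixel-resampling images are drawn uniformly **with replacement** (an
ordinary bootstrap). With replacement keeps the P resamples i.i.d., so
their attribute vectors are independent draws with variance σ²/n per
channel and the within-difference covariance estimate is unbiased.

## NIR pretreatments

Spectra are sample × wavelength absorbance tables (study-like grid: 605
channels over 900–1700 nm; the instrument's nominal 1.32 nm step would give
~607 points, but the variable count used in analysis is 605 and the
generator follows it). Steps:

* **SG(window, degree)** — Savitzky–Golay local least-squares smoothing
  (defaults 5, 2). Edges are handled by evaluating the polynomial fitted to
  the first/last full window, so no channels are lost and the feature count
  is stable across pipelines.
* **D1/D2** — realised as SG derivative filters with the pipeline's SG
  window/degree, matching the `SG+D1` naming convention; plain finite
  differences are available behind `method="diff"`. Derivatives use a unit
  channel step by default (`delta="nm"` rescales per nm); a global rescaling
  is immaterial after column standardization.
* **MSC** — each spectrum is regressed on a reference (default: the column
  mean of the matrix under correction, the standard convention) and the
  fitted affine distortion inverted: x′ = (x − b)/a. MSC is exactly
  idempotent for a fixed reference.
* **MC** — column mean centering, applied to the full matrix under
  analysis.

Pipelines apply left to right and carry their signature (e.g.
`SG+D1+MSC+MC`, the combination that performed best in screening).

## Stage 1: Euclidean screening and ROC

All features are standardized to mean 0, sd 1 (n−1 denominator) over the
full sample table *before* pairing; a zero-variance column is an error
naming the column. Distances are plain Euclidean norms of standardized
attribute rows. The ROC positive class is C1 versus all else (C1 vs C2 only
is an option), with orientation "smaller distance ⇒ positive"; AUC uses
midranks for ties (Mann–Whitney), making it invariant under strictly
increasing transforms of the distances. Pooling across blocks is assumed.

## Stage 2: the Mahalanobis protocol

For images A and B with masks of N_A, N_B pixels:

1. draw P resamples of n pixels per image (defaults P = 100, n = 10% of the
   smaller mask, floor 500, cap N−1);
2. attribute vector per resample;
3. within differences: consecutive disjoint same-image pairs (1−2, 3−4, …),
   pooled over both images → m = 2·⌊P/2⌋ vectors;
4. between vector **d**: difference of the full-mask attribute means;
5. covariance **S** of the within differences (n−1 denominator); the
   between vector can be appended as one extra observation
   (`cov_mode="pooled-with-between"`, the literal step-8 reading) but is
   excluded by default — a single observation adds no stable information
   and inflates **S** under the alternative;
6. D² = (d − w̄)ᵀ S⁻¹ (d − w̄), referred to the upper tail of χ²(p).

Two constructions deserve justification:

* **Same-image pairing.** Differencing resamples *across* images would make
  the within mean converge to the between difference itself, forcing
  D² → 0 for any pair of images — degenerate. The ANOVA analogy (between-
  vs within-treatment variability) requires the within differences to carry
  only within-image variability, i.e. same-image pairs. The cross-image
  mode is kept behind `within_pairing="cross-image"` for audit only.
  Disjoint consecutive pairs (rather than all C(P,2)) keep the m within
  differences independent, so **S** is an unbiased covariance estimate.
* **Resample size and χ² calibration.** A bootstrap mean of n pixels has
  variance σ²/n per channel; the original-image mean has variance σ²/N.
  Under the null (both images from one pixel distribution),
  D² ≈ (n/N + 1/m) · χ²(p): the χ²(p) reference is exact only when n ≈ N.
  The calibration analyses therefore use n = N − 1 (the largest admissible
  resample, since n must stay below the pixel count); at the field default
  n = 0.1·N the test is *conservative* (type-I error ≪ nominal), which
  errs on the side of not discarding a genuinely distinct genotype. With
  n = N − 1 and P = 100, simulated type-I error at nominal 0.05 is ≈ 0.06
  and the null D² sample is indistinguishable from χ²(1) by eye (KS ≈ 0.03
  at 500 replicates) — both recomputed by `scripts/acceptance.py`.

Default attributes are `R` only (p = 1), the band the screening stage
identified as carrying nearly all of the image information; `RGB` (p = 3)
is one flag away. A singular **S** (e.g. two constant images) raises a
`SingularCovarianceError` by default; `singular="pinv"` substitutes a
pseudo-inverse with a warning. The package intentionally does not choose a
decision threshold *h* on D²: D² scales with the number of attributes, so
only the p-value is offered as a transferable decision aid.

## Synthetic data generator

Per channel, in 8-bit intensity units:

    clone mean = base + family effect + clone effect
    leaf mean  = clone mean + leaf effect
    pixel      = leaf mean + pixel noise, clipped to [0, 255]

with independent Normal effects of sd `sd_family` = 3, `sd_clone` = 1.5,
`sd_leaf` = 0.5, `sd_pixel` = 12 at the defaults and base (90, 130, 60).
The ordering family > clone > leaf reflects that full-sib families diverge
more than sibs within a family, which diverge more than leaves of one
plant; pixel texture noise dominates everything, as in real leaf images.
The sds are small relative to the 8-bit range, so clipping affects far less
than 1% of pixels. The leaf is an ellipse (default semi-axes 55 × 90 px in
a 200 × 200 image, ≈ 15.5k leaf pixels) on a bright 245–255 background so
the default segmentation threshold of 240 separates it exactly.

NIR spectra: a smooth quadratic baseline plus 8 Gaussian peaks (width 40
nm) whose amplitudes carry the same family/clone/leaf hierarchy
(sd 0.02 / 0.01 / 0.003 absorbance units around a base amplitude 0.25);
the observed spectrum is a·signature + b with per-leaf scatter
a ~ N(1, 0.05²), b ~ N(0, 0.02²), plus additive noise (sd 0.003). MSC/SG
therefore have real distortion to remove. `spectral_signal_config()` is a
named variant for the regime where genotypes separate by leaf chemistry
rather than visible colour (weak RGB clone/family effects, default NIR
hierarchy) — the setting in which high-dimensional spectral features are
expected to out-discriminate a single band.

Randomness: every family, plot and leaf draws from its own substream keyed
by (seed, kind, family index, block index, leaf index), so enlarging a
design never reshuffles previously generated units, and bundles are
byte-identical for a fixed seed.

**What the simulations do not show.** Leaves are homogeneous ellipses:
no venation, disease spots, shape variation, specular highlights or
illumination gradients, and pixel noise is i.i.d. Gaussian rather than
spatially correlated texture. Passing tests therefore validate the
*statistical machinery* (combinatorics, pretreatment algebra, calibration,
orderings), not field-level accuracy; on real images the within-image
variability is larger and spatially structured, and the protocol's p-values
should be read as a ranking aid rather than exact error rates.

## Problem sizes and numerics

Simulation-based checks use 500 replicates for null calibration (60 × 60
images), the full 861-pair dual-block bundle for class orderings, and three
replicate bundles for scenario AUCs — sizes at which the checked orderings
and calibration bands are stable across seeds. Covariance inversion uses a
direct solve guarded by a condition-number check (10¹²); quantile–quantile
tables use plotting positions (i − ½)/n. Distances, AUCs and the D²
pipeline are deterministic given a seed; batch runs give each pair an
independent spawned substream so results do not depend on pair order.
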
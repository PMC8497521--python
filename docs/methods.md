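# Methods

This note documents the models and procedures implemented in
`plasmidquant`, the tunable parameters and their defaults, what the
synthetic-data generators do and do not emulate, and the numerical and
design choices made where more than one reasonable option existed.

## Reporter logic and units

All three pipelines assume a dual-label reporter: red fluorescence
(mCherry, plasmid-encoded) marks plasmid-carrying cells; green
fluorescence (GFP, chromosomal, de-repressed when the plasmid-encoded
LacI^q is lost) marks plasmid-free cells. Image analysis operates on
*voxels*, not cells: counts, ratios and volumes are voxel-based, with
physical units entering only through the voxel dimensions (dz, dy, dx) in
µm. Volume is voxel count × dz·dy·dx exactly; no sub-voxel interpolation
is performed.

## Image primitives (`imagecore`)

**Median smoothing** is a 3×3×3 filter with edge replication at stack
borders (replication avoids dimming objects that touch the boundary; the
choice matters only within one voxel of the border).

**Auto-thresholding** operates on an explicit histogram: data with ≤256
distinct values get one bin per value, otherwise 256 uniform bins. All
three methods (Otsu's between-class variance, Yen's entropic-correlation
criterion, Tsai's moment-preserving method) are evaluated by exhaustive
scan over candidate cuts; ties break toward the lowest cut, and the
returned threshold is the midpoint between the adjacent occupied bin
centres. Foreground is strictly `intensity > t`, so an all-background
image stays empty and a constant image is rejected as degenerate. The
implementation is hand-written because the Moments method is not available
in the installed image libraries and because the tie-break and strict
inequality conventions needed pinning; Otsu and Yen are cross-checked
against scikit-image in the test suite (agreement within one bin width).

**Connected components** use 26-connectivity by default (face + edge +
corner adjacency, the 3D reading of "grouping adjacent pixels including
diagonals"); 6- and 18-connectivity are available for sensitivity
analysis. Adjacency is voxel-topological: anisotropic voxel dimensions do
not alter which voxels are neighbours, they only enter volume and distance
computations. Labels are deterministic — components are numbered in
raster-scan order of their first voxel (the scipy labeling is relabelled
to guarantee this).

**Channel/algorithm assignment.** Flow-cell stacks are thresholded with
Yen (green) and Moments (red); bead stacks with Otsu on both channels,
after smoothing. Which flow-cell channel gets which algorithm is an
assumption (both orders are plausible); it is configurable under
`flowcell.threshold`. Flow-cell stacks are not smoothed by default;
smoothing is stated only for the bead analysis and a `smooth` flag exposes
the alternative.

## Flow-cell depth profiles (`flowcell`)

Per-layer voxel counts n_free(z), n_carrier(z) define the biomass
B(z) = n_free + n_carrier. Layer positions are recentred by subtracting
the biomass-weighted mean z, so corrected position 0 marks the biomass
centre and different stacks align. Two descriptions of this operation
circulate — "subtract the weighted mean" and "0 denotes the layer with the
most biomass" — which differ whenever the biomass profile is asymmetric;
the implementation performs the weighted-mean subtraction and reports the
modal layer's corrected position (`mode_z_corrected`) as a diagnostic.

Replicate averaging bins corrected positions to unit-layer bins centred on
integers (half-up rounding, so half-integer positions split into distinct
adjacent bins) and averages counts across a replicate's images, absent
layers counting as zero.

The per-layer loss proportion is p(z) = n_free/B, undefined (NaN, never
imputed) where B = 0. The smoothed curve is a LOESS: local quadratic,
tricube kernel, and total weight = tricube × biomass, so dense layers
dominate. Zero-weight points are excluded *before* neighbourhood
selection, making the fit exactly invariant to their values. The default
span is 0.75 (visualisation); parameter-recovery tests pin span 0.1
because a local quadratic over ~4-layer windows is the widest smoother
that can follow a two-plateau step profile within 0.05 — at ≥2000
foreground voxels per layer the per-layer binomial noise (σ ≈ 0.01) is far
below that tolerance, so nothing is lost by the narrow span.

Stratification sums counts over the layers below (bottom) and at-or-above
(top) corrected 0 and forms the free:carrier ratio per stratum; summing
counts before dividing is equivalent to biomass-weighting the per-layer
ratios (the alternative — unweighted mean of per-layer ratios — is
deliberately not the default). The boundary layer at exactly 0 goes to the
top. For symmetric biomass profiles the two strata hold equal biomass up
to the boundary layer's discretization; for skewed profiles the
weighted-*mean* split can deviate from a true half-biomass (median) split
by more than that — a limitation of the mean-based definition itself,
visible in the reported stratum biomasses. Stratum ratios across images
and plasmid variants are compared by an additive two-way fixed-effects
ANOVA (no interaction by default; Type-II sums of squares, which reduce to
the textbook decomposition in balanced designs).

## Bead aggregates (`bead`)

The bead centre is the coordinate-wise median of all foreground voxels
(union of both channels), robust to stray voxels. Channels are labelled
independently; per aggregate the table records voxel count, physical
volume, unweighted centroid (µm) and Euclidean centroid→centre distance
(µm; a voxel-unit alternative would differ under anisotropy — µm is the
default because the 50 µm³ volume rule is physical).

Filtering discards aggregates strictly smaller than 50 µm³ (exactly
50 µm³ is retained) and aggregates outside the bead. "Outside" is manual
in the original workflow; here it is automated as distance
> 1.1 × estimated bead radius, the radius being the 99th percentile of
size-retained aggregate distances (both factors are config keys). Removed
rows stay in the table with a reason. Distances are then normalized per
bead by the maximum *retained* distance (the order filter → normalize is
fixed and tested; normalizing first would let a discarded straggler
stretch the scale).

Summary models: OLS of log10(volume) on normalized distance with a 95%
confidence band, and a random-intercept model
log10(volume) ~ status + (1 | bead) fitted by profile REML, with a
normal-approximation p-value on estimate/SE (no Satterthwaite df
correction — stated explicitly in the output). With a single bead the LMM
falls back to OLS with a warning. Half-bead geometry (beads are cut and
imaged from the cut face) is not modelled; distances are 3D Euclidean in
image space.

## Flow cytometry (`facs`)

The gating strategy is built from single-population controls (a pure
plasmid-carrying and a pure plasmid-free sample): each channel's cut is
the midpoint between the control means in log10 space, and each
population's rectangle extends from its cut to mean ± 3 sd on its own
side, so the two gates are disjoint by construction. Controls whose means
are closer than 2 pooled sd in either channel are rejected as not
separable. Events below both cuts are debris; events in neither rectangle
are left ungated. Loss fractions count only carrier- and free-gated
events, with Wilson 95% intervals. With control populations 3 log-sd
apart, an event is mis-gated only by crossing *both* midpoint cuts
(≈Φ(−1.5)² ≈ 0.45% expected); events landing in no population gate are
excluded rather than counted as errors, as in standard practice.

Trajectories average technical replicates within biological replicates,
keep biological replicates separate, and summarize per day by mean ± SEM.
Trend differences between two strains are the day×strain interaction of an
OLS on replicate-level fractions (day numeric, fractions untransformed by
default; an empirical-logit flag exists for sensitivity). Relative fitness
from competition counts uses the Malthusian-parameter ratio; the raw
counts are always carried in the result so alternative conventions can be
recomputed. Swapping competitors maps w to 1/w exactly.

## Statistical kernel (`stats`)

OLS uses a QR decomposition and reports rank deficiency by column name.
The REML random-intercept fit profiles the criterion down to the variance
ratio λ = σ²_b/σ²_e, solved by bounded one-dimensional minimization over
log λ with the λ = 0 boundary checked explicitly (collapse to OLS); GLS
fixed effects and covariance are evaluated at the optimum via the
per-group Woodbury identity. In balanced one-way layouts the variance
components agree with the classical ANOVA estimators, and fits are
cross-checked against statsmodels MixedLM in the tests. The kernel is
hand-written numpy so that the ≥1000-replicate null-calibration suites run
in seconds; statsmodels serves as the independent oracle, never the
implementation.

## Synthetic data (`synth`)

None of the generative forms below is measured by the experiments they
emulate; they are the simplest models with the statistical structure the
analyses assume, and their defaults are fixed study conditions, not tuning
knobs.

* **Flow-cell stacks**: per layer, round(B(z)) distinct voxels become
  foreground, each green with probability p_loss(z) (binomial channel
  assignment); truth counts equal rendered foreground exactly, before
  noise. Default: 40 layers of 96×96 at (0.5, 0.2, 0.2) µm — plausible for
  a 63×/1.4 oil objective — with B = 2000 voxels/layer (~22% occupancy, a
  confluent biofilm field) and a step profile 0.05/0.30.
* **Bead stacks**: spherical aggregates (sphericity makes volume ground
  truth analytic) at uniform normalized radial distances, with
  log10(volume) = intercept + slope·distance + N(0, 0.2), slope 0.8,
  intercepts 2.6 (carrier) / 2.9 (free) log10 µm³ — microcolonies of
  ~400–3000 µm³, the scale of overnight growth — and rejection-sampled
  non-overlapping placements. Voxels (2, 1, 1) µm suit a 10×/0.30
  objective. The rendered voxel volume differs from the analytic volume by
  less than one voxel per surface voxel (the discretization bound used in
  the tests).
* **Imaging noise** is Gaussian (clipped at 0) on a 12-bit-like scale:
  foreground ≈ 1000 counts, background 10 ± 2. The tight background
  matters: Yen/Moments place their cut a fixed couple of histogram bins
  above the background peak, so the false-positive rate is governed by the
  background sd relative to the bin width (~4 counts at this dynamic
  range). At sd 2 the cut sits ≥4σ out and background leakage into the
  sparse green channel is negligible; at sd 5 (8-bit-like contrast) Yen
  becomes bistable and leaks up to 2% of background voxels, which alone
  would bias the bottom-stratum loss proportion by ≥0.03. This is an
  imaging-contrast assumption of the generator, not a property of the
  analysis.
* **FACS events**: a three-class log-normal mixture (carrier, free,
  debris) in both channels; the default carrier/free separation is 10 sd
  per channel (a clean reporter); gating tests also use the harder 3-sd
  configuration.
* **Loss trajectories**: the deterministic recursion
  f ← (f(1+s) + (1−f)λ) / (f(1+s) + (1−f)) per generation (λ =
  segregational loss probability per division, s = growth advantage of
  plasmid-free cells), applied generations_per_day times per day, then
  binomial sampling of n cells per day. No quantitative loss rates are
  available to parameterize it, so the defaults (λ = 2×10⁻³, s = 0.10 for
  the dispersing strain vs 0.03 for the non-dispersing strain, 10
  generations/day, 4 days) are illustrative conditions that reproduce the
  qualitative pattern (faster loss with dispersal, no conjugation
  effect).

What the generators do *not* emulate: optical point-spread functions and
axial blur, spectral bleed-through, cell-shaped (non-spherical) colonies,
bead-surface truncation of aggregates, conjugative plasmid transfer, and
instrument-specific cytometer artefacts. Passing recovery tests therefore
demonstrates correctness of the quantification machinery under the
generative assumptions, not robustness to every imaging pathology of real
data.

## Numerical conventions

CSV outputs use `%.10g` floating-point formatting; summaries are
sorted-key JSON; every bundle is stamped with a sha256 config hash and the
seed, and identical config + seed reproduce every output file
byte-for-byte (tested, plots included). Sub-seeds for independent
simulation streams derive from the run seed via `SeedSequence` with stable
(CRC-based) tags, keeping all seeds below 2³¹. Degenerate inputs fail
loudly and early: zero-biomass profiles, constant images, non-separable
controls, non-positive competition counts; strata without carrier voxels
or beads without carrier aggregates yield flagged infinities rather than
silent drops.

## Problem sizes in the test and acceptance suites

The recovery suites run on 40×96×96 flow-cell stacks (10 seeds), six
90×200×200 bead stacks totalling 150 aggregates, 10⁴–10⁵ cytometry
events, 1000–2000 null simulations for the type-I-error calibrations and
200 replicates for REML coverage — sizes chosen so the statistical targets
(binomial and Monte-Carlo error well below each tolerance) are met while
the full suite completes in about a minute on one CPU.
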
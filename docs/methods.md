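# Methods

## The measurement model

A field of view of a 2D myelinating culture is represented as two
registered grayscale channels: neurite-stain intensity and myelin-stain
intensity, both in native units of an 8- or 16-bit camera
(M = 2^bit-depth − 1). The quantities of interest are pixel-count ratios
of two binary masks:

* % neurite density = 100 · |neurite mask| / (H·W). Bounded in [0, 100].
* % myelination = 100 · |myelin mask| / |neurite mask|. Unbounded above;
  values > 100 mean the sheath mask outgrew the neurite mask and are kept
  but flagged. If the neurite mask is empty the ratio is undefined and is
  recorded as missing (NaN) — never as 0 or 100 — and excluded from
  condition means and tests while being counted in the per-condition
  summary.

Both masks are deterministic functions of (images, settings); repeated
analysis of the same field is bit-identical.

## Neurite segmentation

Normalize-local-contrast (NLC) followed by a fixed cut. With window
radius r (default 40 px — several neurite widths, so windows see both
structure and background) and sensitivity k (default 3):

    out(p) = clamp( M/2 + (in(p) − μ(p)) · (M/2)/(k·max(s(p), ε)), 0, M )

μ and s are the window mean and standard deviation (uniform filter on the
image and its square; edge-replicated borders), ε = 1 intensity unit
prevents blow-up in flat regions. The optional `center`/`stretch` flags
reduce the transform to `μ(p) + (in − μ)` (identity) when both are off.

The default binarization cut is 0.7·M. Under center+stretch, NLC maps the
local mean to exactly M/2 and k local standard deviations to M, so a cut
at c·M selects pixels more than (2c − 1)·k local SDs above their local
mean: 0.7·M ⇔ 1.2 SD. A cut at M/2 would select *every* pixel above its
local mean — half of any noisy background — so the usable range starts
well above it; 1.2 SD keeps the blurred flanks of neurites while the
subsequent removal of connected components smaller than
`min_object_area` = 10 px deletes the isolated noise pixels such a
permissive cut admits. Because the NLC statistic is a ratio of local
deviations to local spread, multiplying the whole image by a gain g
cancels out of (in − μ)/s and the mask is invariant to global
illumination/exposure changes (verified to < 0.1% drift for g ∈ [0.5, 2]
on phantoms).

Global auto-thresholds (Otsu, mean, triangle, isodata; an extensible
registry) are available as an alternative route; integer-valued images
are thresholded on their integer histogram so the returned cut is an
exact level, with foreground defined as strictly above the cut.

## Myelin-sheath segmentation

Multiscale Hessian vesselness with the bright-ridge branch only. Per
scale σ ∈ {1.0, 1.5, 2.0} px (chosen to bracket half the expected sheath
width; all scales user-settable) the image is smoothed at σ and the
σ²-normalized Hessian eigenvalues λ₁, λ₂ (|λ₁| ≤ |λ₂|) give

    V_σ = 0                                  if λ₂ > 0
        = exp(−R_B²/2β²)·(1 − exp(−S²/2c²))  otherwise,

R_B = λ₁/λ₂, S = √(λ₁²+λ₂²), β = 0.5 (the canonical blobness
sensitivity), and c defaulting to half the maximum Hessian Frobenius norm
over the image and scales. The map is the per-pixel maximum over scales,
clipped to [0, 1]. Images whose maximum Hessian norm is numerically zero
(constant fields) return an all-zero map; the derivative kernels use an
8σ support because the default 4σ truncation leaves the kernel sums
nonzero at the 1e-4 level, enough to fabricate curvature on constant
images once auto-c normalizes it.

The map is binarized at `vesselness_threshold` (default 0.10) and cleaned
by two optional anti-extensive stages, in this order: a binary area
opening removing 8-connected components below `attribute_min_area`
(default 20 px), then removal of a high-intensity mask (≥ 80% of the
native range by default, where cell bodies saturate) dilated by a 2-px
disk. The general grayscale area opening (max-tree pruning) is
implemented behind the same function and reduces exactly to
connected-component removal on binary input.

The vesselness threshold sits where it does for a structural reason: an
isotropic blob has R_B = 1 and therefore V ≤ exp(−1/2β²) ≈ 0.135
regardless of contrast, while ridge responses approach 1. A cut at 0.10
rejects most of the blob plateau (debris speckle, cell-body rims) yet
keeps sheath ridges; cuts at or below 0.05 admit compact debris wholesale
and on debris-heavy fields inflate % myelination severalfold.

Segmentation defaults (the vesselness cut, the NLC cut, the minimum
areas) were calibrated once on the synthetic phantom suite described
below (seeds 0–5), then frozen; tests and the reproduction script run at
these frozen defaults.

## Background correction

Three modes for the myelin channel before sheath segmentation:

* `rolling_ball` (default, radius 25 px): the background is the grayscale
  morphological opening of the image by the ball structuring function
  b(q) = √(radius² − |q|²), edge-replicated borders — the classic surface
  a ball traces when rolled under the intensity landscape. Note that this
  is the true opening (erosion then dilation by the ball); a popular
  shortcut computes only the erosion plus the radius, which overestimates
  the background under thin structures.
* `neurite_mask`: inside the binarized neurite mask the myelin channel
  loses `bleed_fraction` × neurite intensity (clipped at 0), modelling
  spectral bleed-through as proportional to the source channel; outside
  the mask nothing changes. Afterwards all pixels strictly below
  `floor_threshold` are zeroed (removal semantics, not shifting).
  `bleed_fraction` defaults to 1.0 — the worst-case assumption that all
  co-localized intensity could be bleed-through — because masking out the
  signal entirely would also delete genuine sheath signal, which by
  construction co-localizes with neurites.
* `none`: identity.

All modes are anti-extensive and non-negative. Rolling-ball subtraction
is idempotent to within ~1 intensity unit on micrograph-like images
(smooth background + thin structures + moderate noise); on adversarial
inputs such as iid noise the residual of a second pass can exceed that.

## Statistics

The sampling unit is the image: condition comparisons use the per-image
percentages. Pairs of conditions are tested with Welch's unequal-variance
t-statistic and Welch–Satterthwaite degrees of freedom, two-sided. Two
degenerate cases are defined explicitly: two zero-variance samples with
equal means give t = 0, p = 1; one zero-variance sample against a
different mean gives the Satterthwaite limit df = n−1 of the other
sample. The comparison family — all C(k,2) pairs, or the k−1
condition-vs-control tests — is adjusted jointly by Benjamini–Hochberg
(q-values in input order, capped at 1). Aggregation of images into
biological replicates before testing is out of scope; if your design
requires it, aggregate the measurement table first and feed the
aggregates back in.

## The phantom generator

`generate_field` renders what the pipeline assumes a field looks like:

* neurites: 4–6 random waypoints along a random principal direction,
  cubic spline through them, sampled densely, dilated to width 3 px,
  amplitude 120/255;
* sheaths: for each of 5 sheaths, a contiguous run covering 25% of a
  randomly chosen neurite's sampled length, dilated to width ~5 px,
  amplitude 140/255 — giving true % myelination mostly in the 15–40%
  band;
* cell bodies: 2 disks of radius 6 px at amplitude 230/255 (near
  saturation) in the myelin channel;
* bleed-through: 15% of the clean neurite channel added to the myelin
  channel;
* debris: Poisson-placed 3–5 px speckles (1 per kilopixel by default; the
  `demyelinated` preset raises this to 8 and cuts sheath coverage to 10%
  of 2 sheaths, emulating the bright non-sheath residue left after
  complement-mediated demyelination);
* a multiplicative linear illumination gradient (±10% by default) along a
  random direction and additive Gaussian noise (σ = 6/255), clipped to
  the native range.

Ground-truth masks are kept before intensity corruption, and the true
percentages are computed from them with the same metrics code the
pipeline uses, so truth and measurement are exactly commensurable. Each
field consumes one seeded generator; experiment trees derive per-field
seeds from (experiment seed, condition index, field index), so any field
is reproducible in isolation.

What the phantoms do **not** emulate: anti-parallel fasciculation and
neurite crossings at realistic density, sheath intensity variation along
an internode, out-of-focus light, spatially correlated (structured) noise
and camera fixed-pattern artifacts, and stain-specific punctae. Passing
the phantom studies therefore demonstrates internal consistency of the
pipeline and its claimed invariances — not field-ready accuracy on any
particular microscope; on real data the settings profile should be tuned
on a few fields against manual annotation first.

## Validation studies and sizes

The studies in `myelinquant.evaluation` (also run by
`scripts/acceptance.py`) use problem sizes chosen to finish in about a
minute on one CPU while keeping sampling error well inside the margins
being tested:

* ground-truth recovery: 20 default phantoms (256×256) whose true
  myelination lies in 15–40% (sequential seeds, out-of-band fields
  skipped); MAE of both metrics reported in percentage points.
* vesselness vs global Otsu: 10 phantoms at debris density 6/kilopixel;
  median sheath-pixel F1 of both segmentations. The per-field Otsu F1 is
  bistable (its global threshold lands above or below the debris level
  depending on the field's debris-amplitude draw), so the margin between
  the medians varies with the seed window.
* demyelination robustness: 6 `demyelinated`-preset fields; worst
  relative error of % myelination and minimum detected myelin pixels.
* illumination invariance: 3 phantoms × gains {0.5, 1, 2}; worst relative
  drift of % neurite density.
* type-I calibration: a pool of 240 small (48×48) phantoms is measured
  through the full pipeline once; each of 1000 replicate experiments
  draws two groups of 30 % myelination values from that common pool (the
  null is true by construction), applies Welch + FDR, and the rejection
  rate at α = 0.05 is reported. Resampling from a measured pool keeps the
  statistics under test running on genuine pipeline output while staying
  ~3 orders of magnitude cheaper than generating 60,000 fields.

## Numerical and design notes

* Images are held as float64 in native intensity range; integer rounding
  happens only at file-write time.
* Coordinates are row-major, origin top-left, 0-based; connectivity for
  components is 8-neighbour; structuring elements are discrete disks.
* The attribute filter's `min_area` is interpreted on the *binary* mask
  (components smaller than `min_area` pixels vanish), which keeps the
  parameter directly interpretable; the grayscale operator exists for
  users who want map-level filtering before binarization.
* Thresholds are strict where "below" semantics are documented
  (floor threshold: `< floor → 0`; NLC and auto-threshold foreground:
  `> cut`), and inclusive for the cell-body mask (`≥ threshold`).
* Degenerate inputs: constant images raise for histogram-shape
  thresholds (Otsu/triangle/isodata), return all-zero vesselness, and
  map to M/2 under NLC; empty neurite masks make % myelination missing.
* Per-field failures inside an experiment run are logged and excluded;
  the run aborts only when a condition falls below two usable fields.

## Known limitations

* % myelination compares *pixel areas*, so systematic width bias in
  either mask biases the ratio even when every structure is found;
  sheath-length-based metrics are out of scope.
* The vesselness stage responds to any bright curvilinear structure;
  elongated debris chains that mimic ridges survive both cleanup stages.
* NLC invariance holds for global gain changes; it does not correct
  spatially varying gain faster than the window scale.
* Statistics treat images as independent; fields imaged from the same
  well violate this and should be aggregated first.
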
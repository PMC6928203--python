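# Methods

This note documents the models, numerical contracts and design choices
behind `renaldwi`, and what the synthetic validation does and does not
establish about real acquisitions.

## Signal model and units

Every synthetic pixel follows the two-compartment IVIM decay

    S(b) = S0 · ( f·e^(−b·Dp) + (1−f)·e^(−b·D) ),   b in s/mm²,

with S0 ≥ 0 (arbitrary units), perfusion fraction f ∈ [0, 1], and the
constraint Dp ≥ D (pseudo-diffusion of flowing blood is faster than
tissue water diffusion; in tissue Dp exceeds D by an order of
magnitude). D and Dp are *stored and reported* in the conventional unit
10⁻³ mm²/s; the single ×10⁻³ conversion to mm²/s happens inside the
signal/fitting routines, so every user-facing number matches the unit
the field prints. f = 0 reduces the model to the mono-exponential ADC
decay. The default protocol is b = 0, 200, 300, 500, 700 s/mm² in three
orthogonal diffusion directions (15 acquisitions), one coronal slice,
96×96 pixels of 0.47 mm; the phantoms are isotropic, so the three
directions carry identical noiseless signal.

## Phantoms

**Tube phantom.** Three disks (oil, water, acetone) at 120° spacing in
an agarose cylinder, with the literature room-temperature coefficients
0.010, 2.13 and 4.21 ·10⁻³ mm²/s as ground truth and f = 0. The agarose
background diffusivity is not well constrained by the sources the
coefficients come from; it defaults to a water-like 2.0 ·10⁻³ mm²/s at
reduced baseline signal and is configurable.

**Kidney phantom.** A bean shape (ellipse minus a medial notch at the
hilum) partitioned into three nested bands — cortex, outer medulla,
inner medulla — by quantiles of the distance to the organ border, at
area fractions 0.40/0.35/0.25 (cortex outermost; the fractions are a
plausibility choice, as slice-wise layer areas vary with slice
position). Default per-layer ground truth uses the healthy in-vivo
medians D = 1.61/1.78/1.88 ·10⁻³ mm²/s with cortex-dominant perfusion
f = 0.20/0.15/0.10 and Dp = 30 ·10⁻³ mm²/s — f and Dp are not reported
per layer by the benchmark measurements, so representative rodent-kidney
values were fixed once. Background: dim (S0 = 80) slowly-diffusing
tissue surrogate, so threshold segmentation of the organ is realistic
rather than trivial.

## Acquisition artifacts (image-level, not k-space simulation)

**EPI-like warp.** Off-resonance displaces EPI content along the
phase-encode axis. The model: a smooth per-pixel displacement field u
(pixels), applied by pull-back sampling `out(x) = in(x − u(x))` with
linear interpolation for signal images and linear-plus-0.5-threshold
for masks (preserves binarity and tracks the boundary to sub-pixel
accuracy). Random fields are a low-order 2D polynomial plus band-limited
noise, rescaled so max |u| equals the requested amplitude — a stand-in
for susceptibility field maps, which are smooth at the scale of a
kidney. Composing a warp with its negation is only approximately the
identity (the exact inverse requires field inversion); for smooth
fields of ~2 px amplitude the relative L2 error is below 1e−2, which is
the regime the invariance test exercises.

**RARE-like blur.** A fast-spin-echo readout acquires the n-th k-space
line at echo time n·esp, attenuated by exp(−n·esp/T2). The blur is
applied as multiplication of the image's 1D spectrum along the
phase-encode axis by these line weights. Centric ordering (the default,
as diffusion-prepared RARE acquires the k-space centre first) gives DC
gain 1 — total intensity conserved; linear ordering attenuates DC by
exp(−t_centre/T2). Lines at ±ky are assigned the average of their two
weights; the paired lines differ by at most one echo, and the
symmetrization keeps the PSF real and even (no spurious half-pixel
shift). With fewer echoes than lines the acquisition is segmented into
interleaved shots (line of rank q read at echo q // n_segments).
Defaults for the blurred study condition: ETL 192, esp 3.2 ms (the
single-shot protocol's echo train), T2 = 45 ms (typical rat kidney
parenchyma at high field).

**Rician noise.** Magnitude-MRI noise: S → sqrt((S+g₁σ)² + (g₂σ)²)
with iid standard-normal g₁, g₂ from a seeded generator. σ is a free
parameter (acquisition SNR is rarely reported); the study conditions
use SNR = S0/σ = 50. A clipped-Gaussian option exists for analytic
tests.

## Diffusion fitting

**Log-linear ADC (phantom pathway).** Per pixel, OLS of ln S on b over
the five b-values; slope = −D, intercept = ln S0. Pixels with any
non-positive signal among the used b-values are excluded (marked
invalid), not clipped — clipping biases slopes; invalid pixels are
counted exactly.

**Simplified IVIM (in-vivo pathway).** Over b ≥ 200 s/mm² the fast
compartment is attenuated below ~5·10⁻⁵, so `S = A·exp(−b·D)` with
A = S0(1−f). The fit is a per-pixel damped Gauss–Newton least squares,
vectorized across the image: initialization from the log-linear fit of
the same points, D constrained to [0, 50]·10⁻³ mm²/s, step tolerance
1e−10, at most 60 iterations; non-converged pixels fall back to the
log-linear estimate and are flagged. When b = 0 is present, f is
derived from the intercept as 1 − A/S(0), clamped to [0, 1]; Dp is
deliberately not estimated (full three-parameter IVIM fitting is out of
scope). Moving the threshold from 200 to 300 s/mm² changes D by <0.5%
on noiseless IVIM data with Dp ≥ 10·D.

**Direction averaging** is the arithmetic mean of the per-direction
signals at each b before fitting; a geometric-mean option (equivalent
to averaging per-direction diffusivities) is exposed but not default.
At SNR 50 with the full protocol the median relative error of fitted D
is ~2–3% for D ∈ [1.0, 2.5]·10⁻³ mm²/s, for both pathways.

## Border displacement

BD = |A Δ B| / P(B) on *filled* region masks (the mask-subtraction
pipeline defines the computation; masks are reduced to their largest
connected component and hole-filled first). The signed distortion map
is reference − test: +1 false negative, −1 false positive. Two
perimeter estimators:

- `count` (default): number of 4-connectivity border pixels. For a
  digitized convex contour this measures *Chebyshev* arc length
  (≈ 4√2·r ≈ 0.90·2πr for a disk of radius r), so BD of a d-px disk
  shift converges to d/√2 ≈ 0.707·d.
- `crofton`: Crofton-formula arc length (scikit-image), approximating
  Euclidean perimeter, under which the same limit is the analytic
  2d/π ≈ 0.637·d.

Both normalizations are size- and shape-invariant to within ~15% for
shifts small relative to the object; the displacement-simulation
harness (integer 5/10-px shifts, diagonal = (d, d) per axis) tabulates
both. The choice matters only for comparing absolute BD values against
a continuum calculation; within one study it cancels.

## Layer ROIs and statistics

5 cortex + 5 outer-medulla + 3 inner-medulla circular ROIs (default
radius 3 px) are placed deterministically: ring layers get evenly
spaced angular stations on the layer's medial band (deepest admissible
pixels closest to each station angle, lexicographic tie-break); the
inner medulla gets evenly spaced stations along its principal axis. If
a layer cannot host the requested radius, or placements would overlap,
the radius is reduced with a warning; truly impossible placement
raises. This is a simplified, reproducible stand-in for semi-automated
morphology-driven ROI placement; externally supplied ROI masks plug in
through the same container.

Layer statistics follow the ROI-mean convention: ROI mean over valid
pixels → layer mean/median/min/max over ROI means → variability
(SD/mean) and variance (SD²) over ROI means with the sample (n−1) SD.
Whether intra-layer spread should be taken over ROIs or over pixels is
ambiguous in general; over ROI means was chosen because the layer
summaries themselves are defined from ROI averages.

## Group comparison

Median [min; max] summaries; exact two-sided Mann–Whitney U by full
enumeration of all C(n1+n2, n1) rank assignments for groups up to 10,
with mid-ranks (so ties are handled by permutation of the observed rank
configuration), p = 2·min(P(U ≤ u), P(U ≥ u)) capped at 1; the
tie-corrected continuity-corrected normal approximation beyond that,
with the method recorded. Comparison ratios (fold-difference of
medians, percent excess) are stored at full precision; rounding (1
decimal for folds, integer percents, 1 significant figure for p) is
applied only at report rendering.

## The cohort study conditions

Seven subjects per condition, paired design: each subject's phantom
(semi-axes jittered ±8%, centre ±2 px, per-layer D lognormal with 5%
sd) is imaged under an EPI-like condition (smooth warp, amplitude 3 px
— the order of magnitude of in-vivo EPI border displacement — no blur)
and a RARE-like condition (echo-train blur as above, no warp), both at
SNR 50. The observed kidney outline is segmented from the subject's
distorted, noisy b = 0 image (Otsu threshold, largest component, holes
filled) and compared to the true outline via BD; D maps come from the
simplified IVIM fit after direction averaging; ROIs are placed on the
*true* (undistorted) layer masks, as a morphology-based analysis would
place them, so geometric distortion translates into layer-assignment
error. One master seed drives all per-subject/per-condition child
seeds (numpy SeedSequence spawning), recorded in the report;
re-running with the same seed reproduces the report bit-exactly.

Under these defaults the warped condition's BD (median ≈ 0.5 px)
separates completely from the blurred condition's (≈ 0.06 px), so the
exact p attains its floor 2/C(14,7) ≈ 0.0006. Note the absolute BD
values are set by the chosen warp amplitude and field shape, not
calibrated to any measured acquisition.

## What the synthetic validation does not show

- Phantom decays are single-compartment per pixel with spatially
  constant parameters per region; real kidneys have partial-volume
  mixtures, flow/respiration artifacts and T2/T1 contrast the generator
  omits (no relaxation-weighted baseline differences between layers).
- The warp model displaces along one axis with a smooth field; real
  susceptibility distortion also compresses/stretches signal
  (Jacobian intensity modulation is not modelled).
- Intra-layer variability orderings between the two synthetic
  conditions depend on the chosen artifact mix (a 3-px warp against
  ~10-px-wide layer bands vs a long-echo-train blur): in this regime
  blur-induced partial-volume can rival warp-induced layer mismatch,
  so the synthetic study does not reproduce — and is not used to claim
  — any particular in-vivo variability ordering. The pipeline computes
  the comparisons; their direction is condition-dependent.
- Segmentation is a single Otsu threshold against a dim uniform
  background, far easier than outlining a kidney bordered by organs of
  similar intensity.

## Problem sizes

Defaults keep every stage interactive: 96×96 single-slice images, 15
images per series, 1000-pixel noise-recovery simulations, 7+7-subject
cohorts (a full cohort run takes a few seconds). All sizes are
parameters of the respective functions.
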
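# Methods

This note documents the models, estimators and numerical choices
behind `duoscope`, and what the synthetic-data generators do and do not
emulate.

## Focal-plane estimation from the 45° target

A depth-of-field target tilted at 45° maps depth onto lateral
position: one object-space micrometre along x corresponds to one
micrometre of depth. With 15 lp/mm line pairs on the target, the
column-average profile of a trial's time-average frame oscillates at
the 66.67 µm period with a modulation depth that decays with defocus.
The profile is modelled as

y(x) = d + a·exp(−((x−b)/c)²)·(A0 + A1 cos(2πx/ω) + B1 sin(2πx/ω)),

with ω fixed at the line-pair period (66.67 µm for 15 lp/mm). The
envelope centre **b** (µm) is the focal-plane position; **c** (µm) is
the envelope width, set physically by the defocus-blur growth rate.

Numerical choices:

* **Baseline term d.** The target image has a constant background
  pedestal (the mean intensity of the bars), which a purely enveloped
  model cannot represent: without d the width c diverges to flatten
  the envelope and b becomes ill-determined. d enters the linear
  subproblem and costs nothing.
* **a is fixed to 1** — it is not identifiable jointly with
  (A0, A1, B1).
* **Separable least squares.** For fixed (b, c) the coefficients
  (d, A0, A1, B1) are solved in closed form; (b, c) are optimized by
  bounded L-BFGS-B on (b, log c) from a deterministic multi-start grid
  (8 centre starts × 3 width scales, ftol 10⁻¹²). The fit has no
  random state. b is constrained to the profile's x-range.
* **Degenerate input** (zero-variance profile) raises instead of
  returning garbage.
* A dense (b, c) grid search with the same linear subproblem
  (`duoscope.validation.envelope_grid_search`) serves as an
  independent check; the two agree to ≤ 0.15 µm on sweep data.

The control-signal→depth model is ordinary least squares of depth on
PWM duty percent (raw 0–1023 counts convert as counts/1023 × 100).
R² = 1 − SS_res/SS_tot, with R² ≡ 0 (plus a warning) when the depths
have zero variance. The absolute depth origin is configurable
(`x_ref`/`depth_ref`); slope and R² do not depend on it.

## Grid-target geometry

**Intersection detection** correlates the frame with a dark-cross
template (normalized cross-correlation), takes local maxima at ≥ 0.55
grid spacings apart, refines each to sub-pixel by per-axis quadratic
interpolation of the correlation peak, and indexes the lattice after
estimating the grid orientation by a 4-fold circular mean of
neighbour angles (robust to a few degrees of rotation). Because a
field-curved optic cannot hold the whole grid in focus on one frame,
each intersection is then re-localized on the frame where its own
focus score peaks before the distortion fit.

**Distortion** is the single-coefficient radial model
r_obs = r(1 + k r²). After a similarity (Umeyama) alignment of the
ideal lattice onto the detections, radii are regressed as
r_obs = α r + β r³; since the similarity scale s absorbs part of the
distortion (α = 1/s, β = k/s³), the unbiased estimate on the true
radius scale is **k̂ = β/α³**. A pure scale perturbation gives β = 0,
hence k̂ = 0. Per-point Δr is also reported model-free.

**Per-point focus** uses gradient energy (sum of squared first
differences) in a window of side ≈ the grid spacing, with parabolic
interpolation of the score across depth. Points whose score peaks at a
scan boundary are flagged unreliable and excluded from the sphere fit
— their true optimum may lie outside the scan, and including them
biases the curvature.

**Petzval sphere.** The sphere equation is linearized as
x² + y² + z² = 2x₀x + 2y₀y + 2z₀z + d and solved by least squares;
radius = √(d + x₀² + y₀² + z₀²). (Near-)coplanar input — e.g. a flat
field — is detected by the design-matrix condition number (> 10⁸) and
raises a degenerate-fit error; the grid-calibration workflow reports
the degeneracy instead of a bogus radius. A direct nonlinear
minimization of Σ(‖p−c‖−r)² is kept as an independent oracle; the two
agree within 1 % at realistic noise. The scan's reference depth
("depth 0") is the plane where the most intersections score ≥ 95 % of
their own curve maximum.

## Chromatic aberration from beads

Beads are detected per channel in the (z, y, x) volume: light Gaussian
smoothing, local maxima above median + 8 × robust sd (1.4826 × MAD),
minimum physical separation keeping the brighter peak, then sub-voxel
refinement. The default refinement fits a parabola to the
log-intensity along each axis — exact for Gaussian-like bead images
and accurate when the bead is wider than a voxel. The intensity-
weighted 5-voxel centroid and the raw voxel argmax are available as
options; the windowed centroid is biased toward the argmax voxel for
beads wider than ~2 voxels and is not recommended for quantitative
offsets.

Cross-channel pairing is mutual-nearest-neighbour in the **lateral**
(x, y) plane by default (≤ 20 µm): beads sit quasi-planar on the
slide, and the axial offset between channels is precisely the quantity
being measured, so z must not enter the correspondence. Offsets are
red − green; mean and sample sd (ddof 1) are reported per axis, with
sd ≡ 0 and a warning for a single pair.

## Preprocessing

* **De-interleaving**: even sensor frames to the leading channel
  (green by default), odd to the other; per-channel rate = fps/2.
  Re-interleaving round-trips exactly.
* **Median filter**: 3×3, half-sample-symmetric (reflect) edges.
* **Registration**: shift maximizing the plain (unnormalized) Fourier
  cross-correlation, sub-pixel by locally upsampled DFT. Sign
  convention: the returned (dx, dy) is the frame's displacement, so
  applying (−dx, −dy) aligns it to the reference. A bounded search
  mode masks the correlation surface to |shift| ≤ a prior bound and
  refines the peak by clamped quadratic interpolation — used where the
  physical displacement is known to be small (cross-channel offsets)
  and unrelated content could otherwise produce a spurious far peak.
* **Motion correction**: two-pass (first frame → provisional average →
  final reference), spectral (Fourier) resampling for fractional
  shifts, integer rolling as a strict mode. The corrected trial is
  anchored at its mean position. Note that two channels corrected
  independently still differ by the sampling error of their mean
  jitter (≈ √2·σ/√n), which the cross-channel average-image
  registration step removes; the session pipeline always performs that
  step before matching.

## Dual-channel segmentation and matching

The red (static) channel is segmented from its corrected average
image: high-pass (subtract Gaussian, σ = 8–10 px), binarize at
median + 4 × robust sd, connected components filtered to
20–800 px, weights = high-pass intensities on the support. The green
channel is segmented the same way from its PNR image
((max − median)/robust sd per pixel; 0 for constant pixels) with a
threshold factor of 3 — PNR backgrounds are flat, and dim or
rarely firing somata otherwise survive only as sub-minimum-area
islands. In crowded fields touching somata merge into one component;
`split_touching` runs a local-maxima-seeded watershed inside the
binary mask (the session pipeline enables it). Footprints from an
external source-extraction tool (e.g. CNMF) can be substituted; the
built-in detector is deliberately simple.

The binary support of a footprint is weights ≥ 50 % of its maximum
(configurable). Overlap is |A∩B| / min(|A|, |B|) — the soma-in-soma
reading of a "minimum 50 % overlap" criterion — with
intersection-over-union as an option. Matching is greedy in
descending overlap with deterministic tie-breaks (centroid distance,
then label order); a Hungarian-algorithm optimal assignment is kept as
a validation oracle and differs from greedy on < 5 % of pairs in
practice. The matched percentage divides matched pairs by a chosen
channel's total.

Cross-channel registration uses the two channels' high-passed average
images (shared content: vasculature and co-labelled somata) with the
bounded search (±15 px), then refines by the median centroid
displacement of loosely matched (≥ 0.3 overlap) pairs. Session maps
average each neuron's aligned per-trial footprints over the trials
where it was detected. Longitudinal tracking registers and matches
each later session against the first (unbounded search: revisited
fields share most content and drift can be large), producing one
chain per session-1 neuron.

ROI traces: weight-normalized mean over the support; neuropil = plain
mean over a 2–6 px dilation annulus excluding all footprint supports,
subtracted with factor 0.7 (configurable; 0 disables); ΔF/F uses the
20th percentile of the corrected trace as F0.

## Synthetic data: what it emulates, and what it does not

The generators produce every bench acquisition with exact ground
truth. Defaults are the study-scale conditions: 7.7 µm focal shift
per percent duty (770 µm over 0–100 %, 24-trial sweeps, 100-frame
trials), 25 µm grid scanned 36 × 9.6 µm, Petzval radius 343.1 µm,
radial k = 10⁻⁶ µm⁻², chromatic offset (0.5, 0.5, −123.7) µm,
15 µm beads, 10 fps interleaved sessions, GCaMP6f-like transients
(Poisson events, instant rise, τ = 0.5 s exponential decay), ~3.3×
magnification at 4.5 µm sensor pixels.

Deliberate modelling choices:

* **Defocus blur** is an isotropic Gaussian with σ growing linearly at
  0.25 px/µm of defocus, floored at the device's measured optical
  resolution (4.4 µm FWHM). The real EWL+GRIN blur law is
  uncharacterized; this is a monotone stand-in, so absolute envelope
  widths c are not transferable to real hardware — only the centre b
  is meaningful, and that is all the depth model uses.
* **The line-pair target** is rendered as a sinusoidal grating by
  default, matching the first-harmonic measurement model. With square
  bars (`profile="square"`, like the physical Edmund target) the
  unmodelled odd harmonics bias b by up to ~2 µm at this blur gain —
  a caveat that applies to real bar targets as well.
* **Sessions** include static red somata, dynamic green somata with a
  visible GECI baseline (0.35 of transient amplitude), per-frame rigid
  jitter shared by both channels, Gaussian sensor noise, and a static
  multiplicative vascular-shadow field common to both channels — the
  shared anatomy that makes cross-channel average-image registration
  well-posed, as it is in real tissue. Somata are placed with a
  minimum separation of 2.8 soma radii; the field of view (300² px)
  holds 140 neurons at realistic density.
* **Beads** are quasi-planar (20 µm axial band), as on a physical
  bead slide.

Not emulated: wave optics and vignetting, sensor noise physics
(photon shot noise, fixed-pattern noise), non-rigid tissue motion,
neuropil contamination with its own dynamics, overlapping somata at
depth, and bleaching. Passing tests therefore demonstrate estimator
correctness under the stated generative model, not robustness to
every pathology of real one-photon data; the pipeline's behavior
under non-rigid motion or heavy neuropil is untested here.

## Problem sizes and determinism

The shipped tests and the acceptance script use the study-scale
designs where they are cheap (24-trial sweeps, 36-depth grid scans,
20-seed bead studies, 400-frame sessions with 100 + 40 neurons,
5-session tracking) and smaller scenes for unit tests; all sizes are
stated at the call sites. Every generator is deterministic given
(parameters, seed); the CLI pipeline writes byte-identical result
files for identical config + seed (provenance timings excepted).
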
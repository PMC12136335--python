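# Methods

This note documents the models, the numerical choices and the defaults
behind `vckulm`, and what the synthetic phantom does and does not emulate.

## Coordinates and containers

All positions are 0-based pixels with `x` the column index and `y` the row
index, origin top-left. Velocities are px/frame unless a frame rate is
applied (then px/s). A movie is a `FrameStack`: a `(n_frames, rows, cols)`
float array with `frame_rate` (Hz) and `pixel_size_um` metadata, read and
written as multipage 32-bit TIFF or HDF5 (`/frames` with attributes).

## Flow phantom

The generator composes each frame as

```
frame(t) = shift( clutter(t) + bubbles(t), d(t) ) + noise(t)
```

* **Bubbles.** Spawns per vessel per frame are Poisson with mean
  `bubble_rate`. Each bubble advects along the vessel centerline
  (arc-length parameterization, linear interpolation between control
  points) at the vessel's constant `flow_speed`, carries a constant
  brightness drawn uniformly from `brightness_range`, keeps a constant
  lateral offset within ±0.8·radius of the centerline, and dies on leaving
  the grid. Rendering is an isotropic Gaussian PSF of width `psf_sigma`
  (default 1.2 px) evaluated at the exact subpixel position.
* **Clutter.** A sum of `clutter_rank` separable spatial patterns
  `(1.1 + cos)(1.1 + cos)` with 2–6 cycles across the grid, each modulated
  by a slow temporal sinusoid (period 3–6 movie lengths, depth 0.15). The
  Casorati matrix of the clutter is exactly rank `clutter_rank` in the
  absence of motion, so SVD filtering provably removes it. The spatial
  frequencies are high enough that block matching sees a well-defined
  correlation peak — tissue in B-mode is textured, not flat.
* **Motion.** A global sinusoid `d(t) = (ax, ay)·sin(2πt/period)` applied
  to clutter and bubbles by bilinear resampling; noise is added after the
  shift (sensor noise does not move with tissue).
* **Ground truth** records the pre-motion bubble tracks, the applied
  per-frame shifts, a super-resolved vessel mask, and the three scene
  layers separately for component-wise energy bookkeeping in tests.

A warning (not an error) is raised when the mean nearest-neighbour bubble
spacing falls below `2·psf_sigma`, where the one-peak-per-bubble
localization assumption starts to fail.

Not emulated: RF-domain physics, beamforming, speckle statistics of real
tissue, nonlinear bubble acoustics, flow profiles across the lumen
(plug flow only), out-of-plane motion. Passing tests therefore demonstrate
algorithmic correctness and the direction of effects, not in-vivo image
quality.

## SVD clutter filter

Each chunk of `chunk_size` frames (default 200, bounding memory) is
reshaped to a Casorati matrix (pixels × frames); the leading
`n_tissue_components` singular components are zeroed; the magnitude of the
reconstruction is kept (localization needs nonnegative brightness) and
values below `noise_threshold` are set to zero. The threshold is estimated
by `estimate_noise_threshold` as a percentile (default 99th) of the
filter residual on a bubble-free control stack. The rank cutoff is a fixed
integer — no automatic elbow detection; with global tissue motion the
clutter is no longer low-rank and more components must be removed
(the motion study removes 8), which is one reason motion compensation
matters.

## Localization

Peaks are strict 8-neighbour local maxima of the Gaussian-smoothed frame
(default sigma 1.0 px) at or above `min_peak_intensity`; peaks closer than
`min_peak_separation` (default 3 px) are merged greedily by descending
intensity. In practice the peak threshold should sit well above the SVD
noise floor (the examples use 4×), otherwise noise bumps riding on bubble
tails are reported as bubbles.

The subpixel offset along each axis comes from the three samples
`I(−1), I(0), I(1)` through the cosine model `I(u) = A·cos(α(u−ξ))`:

```
α = arccos((I(−1)+I(1)) / (2 I(0)))
β = arctan((I(−1)−I(1)) / (2 I(0) sin α))
ξ = −β/α, clamped to [−0.5, 0.5]
```

The arctan form of β is the exact algebraic inverse of the model: for a
true cosine profile `(I(−1)−I(1))/(2I(0)sinα) = tan(β)` and symmetric
profiles give exactly β = 0. An arccos form of β is available behind
`beta_form="arccos"` for comparison; it cannot return 0 for symmetric
profiles and is not exact, so arctan is the default. Degenerate inputs
(non-strict peak, arccos argument outside [−1, 1] beyond 1e−12, sin α = 0)
fall back to the integer position and are flagged.

On a Gaussian PSF the cosine fit is not exact but biases stay below
~0.05 px for the default widths; the test suite pins < 0.1 px on noiseless
blobs and < 0.2 px on phantom frames.

## Tracking

State `S = [x, y, I, dx, dy]` with constant-velocity, constant-brightness
transition F and observation H on `(x, y, I)`. Process noise Q is diagonal
(`q_pos` 0.05 px², `q_vel` 0.05, `q_I` 0.5), measurement noise R diagonal
(`r_pos` 0.05 px², `r_I` 1.0). The covariance update is the standard
`P = (I − KH)P⁻` followed by symmetrization; it satisfies the textbook
limits (K→0 keeps the prediction, K→identity adopts the measurement),
which the tests verify together with 1D hand algebra for the equal-variance
midpoint.

Association is a per-frame global minimum-cost one-to-one assignment
(`scipy.optimize.linear_sum_assignment`) over pairs within `gate_radius`
(default 5 px) of the predicted position, with cost

```
cost = d/gate_radius + λ·|I_pred − I_det|/brightness_scale
```

(λ default 0.5; `brightness_scale` defaults to the median detection
brightness). Greedy nearest-first matching is deliberately avoided — two
crossing bubbles with distinct brightness must not be swapped.

New tracks start with zero velocity and a large velocity variance
(25 px²/frame²); from the second point on, velocity is seeded by the
*statistical velocity* — the mean of the up-to-3 most recent observed
per-frame displacements — which also re-seeds tracks whose prediction
failed to find a detection. Unmatched tracks coast on their prediction for
up to `max_coast` frames (default 1, bridging single-frame dropouts) and
then terminate. Tracks shorter than `min_track_length` detections
(default 5) are discarded.

The nearest-neighbour baseline (`track_stack_nn`) matches greedily by
distance from the last observed position, has no prediction, no brightness
term and no coasting — it is the traditional-ULM comparison point.

## VD trajectory rejection

`VD = Σ|vᵢ| / |Σ vᵢ|` over a trajectory's step vectors; 1 exactly for
collinear same-direction steps (triangle-inequality equality), +∞ when the
steps cancel. Tracks with VD > `vd_max` (default 2, i.e. more than 100%
deviation of summed step length from net displacement) are discarded.
Two evaluation modes exist: one VD per full track (default), or a sliding
window of w ≥ 3 consecutive points where any violating window rejects the
track. The windowed mode catches localized corruption that a long track
averages away — in particular *end-of-life mislinks*, where a bubble that
left the field of view is linked to the next bubble behind it: one large
backwards step barely moves the full-track VD of a long trajectory but
sends a 3-point window far above 2. The pipeline's method-comparison
studies therefore run VD with window 3.

## Motion compensation

Displacement of each frame relative to the middle reference frame is
estimated block-wise (default 32 px blocks, stride 32, integer search range
±4) by maximizing

```
R_nc(δ) = Σ S_r·S_d(·+δ) / √(Σ S_r² · Σ S_d(·+δ)²)
```

computed *without* mean subtraction (a zero-mean variant is available
behind `zero_mean=True`). Window energies come from 2D prefix-sum tables,
making each candidate shift O(block) instead of O(block·window); the
equivalence with the direct double sum is pinned to 1e−10 in tests.

Instead of sweeping the full range for every block, the search exploits
the spatial and temporal continuity of tissue motion: frames are processed
outward from the reference; each block's integer search starts from the
best already-estimated neighbour (left/up block of the same frame, else
the same block of the temporally adjacent processed frame) and hill-climbs
over 3×3 neighbourhoods until a local maximum. On smooth motion this
returns the exhaustive answer (≥ 99% block agreement is an acceptance
property; adversarial discontinuous motion can break it and is reported,
not hidden). Deterministic tie-breaking prefers higher correlation, then
smaller displacement, then scan order.

The integer peak is refined per axis by the 3-point parabolic vertex
`ξ = (R(−1)−R(1)) / (2(R(−1)−2R(0)+R(1)))`, clamped to ±0.5. Two
numerical guards: the block grid keeps a one-pixel margin beyond the search
range so boundary peaks can still be refined, and a perfect-correlation
peak (R ≥ 1 − 1e−9, the Cauchy–Schwarz equality case of an exact match) is
accepted as-is — interpolating around it could only move an exact integer
answer away.

Zero-energy blocks copy their seed displacement with correlation 0 and a
flag. Detections are aligned by subtracting the bilinear interpolation of
the (dx, dy) grids at their position (clamped to the block-centre hull);
compensation is applied to detections before tracking by default, with a
post-hoc track-shifting mode available.

Motion estimation runs on the raw stack, not the SVD-filtered one: the
tissue signal carries the motion. Consequently bright moving bubbles can
bias the correlation peak of blocks they occupy; with tissue-dominant
echo (as in B-mode) the bias is negligible, which the motion study's
phantom reflects (bubble peak ≈ clutter level).

## Maps and metrics

Accepted tracks are accumulated on a grid upsampled by `sr_factor`
(default 8). Each consecutive point pair deposits samples at most one SR
pixel apart along the segment (start inclusive, end exclusive; the final
track point is deposited once), each sample carrying the step's signed
speed (positive toward +y, falling back to the x sign for horizontal
steps). Within one segment a pixel receives at most one sample — repeated
deposits of the same step velocity into one pixel would dilute the
per-pixel velocity statistics with zero-variance duplicates. Total density
equals the number of deposited samples exactly.

`CNR = (E_V − E_N)/σ_N` on the density map between two disjoint region
masks. `regions_from_vessel_mask` builds them from the phantom's vessel
mask: the vessel region is the mask itself and the noise region is the
2–24 SR-pixel annulus outside it — the band where localization jitter,
mislinks and uncompensated motion deposit spurious density.

Per-pixel `nRMSE = √(Σ(Vᵢ−V̄)²/N)/|V̄|` over pixels with ≥ 2 samples and
nonzero mean; the image-level value is the unweighted mean over valid
pixels (a density-weighted mean is available). The statistic presumes
steady flow through the pixel, so when a region mask is supplied only
pixels inside it (in practice: the vessel mask) contribute; pixels with
zero mean are excluded and counted.

Track summaries report mean trace length (detections), mean trace duration
(seconds) and mean flow speed (px/s). Duration and px/s speed are the
frame-rate-invariant quantities: under perfect tracking they do not change
when the movie is temporally subsampled, so their degradation under
subsampling isolates matching failures.

## Phantom studies

Three fixed study designs (`vckulm.studies`) exercise the pipeline end to
end at desk scale; only the seed varies between runs.

* **Tracking study** — 128×128, 500 frames, 8 vessels with flows
  1.5–3.6 px/frame, ~20–30 concurrent bubbles, clutter and noise, no
  motion. Measures link-identity F1 and in-vessel velocity nRMSE for the
  vc-Kalman tracker vs the nearest-neighbour baseline. The regime is fast
  flow at moderate concentration, where nearest-position matching is
  ambiguous but prediction is not.
* **Motion study** — 800 frames, tissue-dominant echo (clutter amplitude
  12 vs bubble brightness 10–14, matching B-mode contrast), sinusoidal
  motion of (1.5, 3.0) px with a 25-frame period. The reference frame falls
  on a zero crossing of the sinusoid, where tissue *velocity* is maximal —
  the worst case for uncompensated velocity estimates. Compares CNR and
  nRMSE across baseline / vc-Kalman / vc-Kalman + compensation; the
  expected result is strictly increasing CNR and strictly decreasing
  nRMSE.
* **Frame-rate study** — 600 frames, flows 1.0–1.7 px/frame; stride-3
  subsampling emulates a 440 → 146.7 Hz acquisition and stretches
  inter-frame steps to 3–5.1 px, toward the 5 px gate but not beyond it.
  Reports the relative change of mean trace duration/length and mean flow
  speed for both trackers. This analysis keeps tracks down to 2 detections
  so that fragments created by broken links remain in the statistics —
  with a higher length floor the mean is distorted by survivor bias
  (dropped fragments make the surviving tracks look longer).

Problem sizes (hundreds of frames, 128×128 grids) are deliberate desk-scale
choices; the pipeline itself is chunked and streams per frame, so larger
inputs only cost time.

## Known limitations

* Overlapping bubbles (closer than ~2 PSF widths) are localized as a single
  merged peak; no demixing or deconvolution is attempted.
* Block-wise translation cannot represent large non-rigid deformation;
  the method targets small respiration-scale motion, not cardiac-scale.
* The continuity-seeded search can lock onto the wrong basin under
  discontinuous or aliased (periodic-texture) motion; the equivalence
  report makes such disagreement visible.
* The SVD rank cutoff and noise percentile are fixed configuration values;
  no automatic selection is provided.
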
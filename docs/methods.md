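# Methods

This note documents the model as implemented: its assumptions, the
parameters that matter, the numerical choices, what the synthetic phantoms
do and do not establish, and known limitations.

## Image model and data term

The segmentation domain is a 2D image or 3D volume of scalar intensities
with per-axis voxel spacing (`ImageGrid`).  The contour is the zero level
set of φ, positive inside.  Around each narrowband point x the intensities
of each side of the contour within the Euclidean ball Ω_x of radius r(x)
are summarized by a Gaussian (μᵢ(x), σᵢ²(x)), i = 1 interior, 2 exterior.
The data force at x is the log Bayes factor of x's own intensity under the
two local Gaussians.  Three stabilizers matter in practice:

* **Variance shrinkage.** Windowed variances are shrunk toward the side's
  global variance with a pseudo-count of 25 voxels.  Without it, windows
  that overlap one side by only a handful of voxels produce wild variance
  MLEs whose likelihood ratios (|log BF| ~ 10²–10³) pin the contour at
  single noise excursions.
* **Force clipping.** The log Bayes factor is clipped at ±`force_clip`
  (default 10, dimensionless).  On noise-free images variances sit at the
  floor and unclipped ratios reach ~10³–10⁴, which starves the CFL time
  step without changing any sign.
* **Intensity-channel smoothing.** The evolution operates on a lightly
  low-passed copy of the image (Gaussian, σ = 1 voxel) whenever the
  wavelet-estimated noise exceeds 1% of the dynamic range, and on the raw
  image otherwise.  A per-voxel Bayes force on raw noise stalls the front at
  isolated dark voxels; conversely, smoothing a noise-free image while the
  interior variance sits at the floor rejects the blurred edge band, hence
  the automatic switch.  Mixture-model variances are contracted by the
  analytic white-noise low-pass factor (4πσ_s²)^(−d/2) so the Bhattacharyya
  comparison stays on the same scale.  σ² floors at (0.01 × dynamic range)².

A literal ratio-of-integrals data term (each side's mean likelihood over its
window portion, the direct reading of the posterior factorization) is
available via `EnergyParams(intensity_force="integral")`.  It is exactly
stationary on perfect partitions but an order of magnitude slower and much
weaker as a driving force; the pointwise Bayes factor is the default.

## Adaptive localization scale

A K-component Gaussian mixture is fitted to the global histogram by EM
(scikit-learn, k-means++ initialization, 5 restarts, seeded; intensities
subsampled to ≤ 2×10⁵ values).  The brightest component is the blood pool
(contrast-enhanced blood), overridable.  K = 3 by default — the
air / soft-tissue / blood-pool structure of a contrast CT histogram — and
K = 3 is also markedly more robust than K = 2 on two-mode images with a
small bright fraction, where a spare component absorbs background
substructure instead of splitting the blood mode.

Each iteration, every narrowband point's interior statistics are compared
with the blood pool by the closed-form Gaussian Bhattacharyya distance, and
the window radius is updated as r = min_scale + max_scale·exp(−τ·D_B),
quantized to whole voxels and clamped to [min_scale, min_scale+max_scale].
Defaults: min 4, max 10 voxels (so r ∈ [4, 14]), τ = 1.  Windows holding no
interior voxels keep their previous radius.  min_scale is conventionally
set to the largest expected vessel radius.

Measured behavior: radii are maximal where the interior matches the blood
pool, shrink monotonically with D_B, and are systematically smaller over
low-contrast vessel segments than over bright ones.  One caveat is
documented honestly: on a tube whose contrast fades along its length, a
*larger* fixed window reaches farther distally than the adaptive schedule,
because the exterior statistics of a small frontal window are dominated by
the not-yet-claimed vessel directly ahead, collapsing frontal contrast
exactly where the adaptive rule shrinks the window.  The adaptive scheme's
measured benefit is locality (boundary accuracy, radius ordering), not
frontal reach, under this data term.

## Tubular shape prior

For every interior voxel, intensities are sampled in n_directions = 36
directions at radius R (equally spaced angles in 2D; a Fibonacci-sphere
point set in 3D; linear interpolation, nearest-edge padding).  The profile
is min-shifted, regularized with ε = 10⁻⁶ of its own dynamic range, and
normalized to a probability vector; its Shannon entropy H ∈ [0, ln n]
rescales to the vesselness v = 2H/ln(n) − 1.  A constant profile normalizes
to uniform (v = +1): flat surroundings are maximally non-tubular.

Two implementation choices make the score usable on noisy images:

* **Bright-membership channel.** Profiles are sampled not on raw intensity
  but on w = logistic((Ĩ − θ)/s), Ĩ the lightly smoothed image,
  θ = min(μ_b − 2σ_b, midpoint of the blood mode and the nearest darker
  mode), s = σ_b/4.  On raw intensities the min-shift normalization hands
  every dark direction a noise-proportional mass, which at contrast = 4σ
  erases the tube/blob entropy separation almost completely (measured
  Δv ≈ 0.04); on the membership channel the separation is Δv ≈ 0.3–0.5.
* **Calibrated neutral score.** With R = 2× the maximal vessel radius, an
  ideal tube subtends about a third of the directions and scores
  v ≈ +0.45, not 0: with this normalization any structure whose arc
  fraction exceeds n^(−1/2) has positive v, so the raw sign of v cannot
  separate tubes from blobs.  The erosion force is therefore pivoted at a
  neutral score v₀ placed 60% of the way from the ideal-tube score (computed
  from the sampler's own direction set, `reference_tube_score`) to the
  flat-profile score +1.  The margin leaves oblique segments, bifurcations
  and vessels brushing adjacent bright structures below the erosion
  threshold.

The shape force is a one-sided hinge: S(x) = Σ over interior∩window of
max(v(y) − v₀, 0)·w(y), entering the flow as −λ·S clipped at `force_clip`.
Two rejected alternatives motivated this form: a window-*mean* erosion
(≤ λ·0.3 ≈ 0.12) can never beat the data term at a leak front (≈ +2–3), so
λ = 0.4 suppresses nothing; a two-sided window-*sum* makes tubular interiors
exert an expansion ≈ λ·n·|v| that overwhelms the data term and dilates the
contour into the background.  The hinge is ≈ 0 on tubular interiors (no
runaway) and saturating-strong inside blob-like ones.  Gating by the
membership w keeps faint distal vessel segments — whose membership profile
is flat *dark*, also maximal entropy — from being eroded: darkness is the
intensity term's business.  v(x) depends only on the image, so scores are
computed once per voxel on first entry into the interior and cached.

## Level-set numerics

* φ is initialized as the signed Euclidean distance to the seed mask
  (positive inside) and redistanced against the *interpolated* zero contour
  (marching squares/cubes at level 0 + KD-tree distances) every 10
  iterations.  Preserving the subvoxel interface position is essential:
  redistancing from the voxel sign mask snaps the interface to mid-voxel
  and erases slow front motion accumulated between reinitializations,
  deadlocking weak fronts.  Signs are preserved exactly; the zero set moves
  only by interpolation error (measured ≲ 0.03 voxel on smooth interfaces).
* Smoothed Heaviside/Dirac: H_ε = ½(1 + (2/π) arctan(φ/ε)), δ_ε = H_ε′,
  ε = 1.5 voxels.  Curvature by central differences.
* Explicit Euler step, dt = 0.5 CFL-capped so no voxel moves more than 0.45
  per step.  Convergence: sign flips summed over a 25-iteration window fall
  below 10⁻⁴ of the narrowband (per-iteration tests fire in the gaps
  between front-advance bursts).  max_iters defaults to 800.
* Narrowband half-width = max window radius + 2; full-domain mode exists
  for tests.  Windowed sums use FFT convolution with ball kernels, with the
  image-only convolutions cached per radius.
* The reported per-iteration energy uses the sharp partition {φ > 0} for
  the data term (the ε-smoothed Heaviside tails against near-degenerate
  variances would dominate the bookkeeping); on noise-free inputs it is
  nonincreasing to within 1% of its range during boundary refinement on a
  fixed domain.  The ‖∇φ‖ = 1 ± 0.1 property after reinitialization holds
  pointwise away from the interface and at the 95th percentile over the
  whole narrowband: central differences necessarily kink at interface
  vertices of a discrete contour.

Default weights follow the method's standard operating point: λ = 0.4
(shape), μ = 0.2 (length).  The localized Chan–Vese baseline mode is λ = 0
with a fixed window radius (default min+max).

## Phantoms: what they emulate, and what passing tests do not show

`make_phantom` builds bright tubes (straight, Y-bifurcation at a given
angle, or linearly fading contrast) of known radius on a darker background,
optionally with a tangent bright blob of the *same* intensity as the vessel
— the leak trap: no intensity boundary separates vessel from blob, so only
shape information can.  Ground truth is the analytic tube support
(distance-to-centerline ≤ radius), computed before noise and independent of
it; the blob is excluded from the truth mask and counts as false positive.
Defaults: vessel radius 4 voxels, contrast = 4× the noise σ (25), blob
radius 3× the vessel radius, tangent (gap 0), i.i.d. additive Gaussian
noise.  `make_trimodal_volume` assigns voxels to three Gaussian intensity
modes (defaults −900/50/350, air / soft-tissue / blood-pool analog) with
vessel and blob forced into the brightest mode, for mixture-recovery tests.

The phantoms are deliberately minimal: piecewise-constant tissue, white
noise, straight or single-bifurcation geometry, no partial-volume ramps, no
streak or beam-hardening artifacts, no anatomical curvature or caliber
variation.  Passing the suite therefore demonstrates the *mechanisms*
(adaptive radius responds to contrast, the shape prior suppresses leaks the
data term cannot, sub-voxel boundary accuracy on clean edges) — not
clinical-grade performance on real angiograms.

## Problem sizes and measured outcomes

The test suite and the acceptance script run 128×128 phantoms for the
end-to-end experiments (a few hundred to 800 iterations, tens of seconds
per run on one core), 40³ volumes for mixture recovery, and 32³ volumes for
the 3D smoke path.  Representative measured values (seed 1): clean-tube
Dice 1.0, noisy-tube Dice 0.999 at contrast 4σ; on the leak phantom the
baseline's FP is 0.45 vs 0.012 for the full model at λ = 0.4 (Dice 0.82 →
0.97), and FP decreases monotonically over λ ∈ {0, 0.2, 0.4, 0.8}; EM
recovers all three trimodal means within 0.5%; two identical runs agree on
every voxel.

## Known limitations

* Frontal reach on fading vessels favors larger windows under the pointwise
  Bayes data term (see above); the adaptive schedule does not extend the
  segmented centerline beyond the fixed-large-radius baseline on that
  phantom.
* The printed vesselness is calibrated by v₀ rather than sign-interpretable
  on its own; compare v against `neutral_vesselness(...)`, not 0.
* 3D support is functional (all operators are dimension-agnostic) but tuned
  far less than 2D; expect to adjust scales and iteration budgets.
* Topology is unconstrained: the contour may split or merge freely.
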
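# Methods

This note documents the models, conventions and parameter choices behind
`lungreg`, and what the synthetic tests do and do not establish.

## Coordinates and geometry

Volumes are arrays in `(x, y, z)` order with 0-based voxel indices; world
coordinates are millimetres via `world = origin + index · spacing`. Every
keypoint, landmark and spline operates in world mm, so anisotropic input
spacing cannot leak into distances or thresholds. Both inputs are resampled
to isotropic spacing before detection (default: the *maximum* input spacing,
i.e. in-plane resolution is reduced to the slice spacing — the cheap
direction for thick-slice CT; trilinear interpolation, nearest-neighbour for
masks). The output grid preserves physical extent `shape · spacing` to
within one voxel.

## Detector

Gradients are Gaussian-derivative filters (σ_g, default 1.0 voxel), with the
derivative kernel rescaled so a linear ramp differentiates exactly despite
truncation. The structure tensor sums gradient outer products under a
separable, **unnormalised** truncated Gaussian window (σ_w, default 1.5
voxels, radius ⌈3σ_w⌉) — a weighted sum, not a weighted mean, so the tensor
scales with local gradient energy. The response is the smallest eigenvalue
λ₃, the direct operationalisation of "all three eigenvalues large"; a
classical `det − k·trace³` variant is available (`response_method="harris"`,
k = 0.05). An ideal plane has a rank-1 tensor (λ₂ = λ₃ = 0), an ideal tube
rank 2, so only genuinely 3D corners (bifurcations, corner points) score.

Selection: 26-neighbourhood local maxima above a threshold (absolute, or a
fraction of the masked maximum — default 5 % — because an absolute scale is
meaningless across intensity conventions), visited in descending response
with lexicographic tie-breaks, accepted greedily when farther than
`min_distance_mm` (default 5 mm) from all accepted points. Voxels within the
filter support of the border (at least 9 voxels, the descriptor half-window)
are excluded.

## Descriptor

2048 components: 4×4×4 spatial subregions × 8 azimuth × 4 elevation bins of
45°. Azimuth ∈ [0°, 360°) from +x in the x–y plane, elevation ∈ [−90°, 90°]
toward +z; right-open bins, +90° in the top band; a zero gradient
contributes nothing. The 16³ window spans offsets −8…+7 (an even window has
no centre voxel). Magnitudes are weighted by an isotropic spatial Gaussian
(σ = 8 voxels, half the window, standard SIFT practice). Hard bin
assignment by default — soft trilinear orientation binning is a config
switch; a single L2 normalisation, no gradient clamping. There is **no
dominant-orientation frame**: breathing motion is locally near-translational
and an axis-aligned frame keeps descriptors comparable; the descriptor is
therefore not rotation invariant by design. Keypoints whose window leaves
the volume are rejected (`zero-pad` optional).

## Matching cascade

* Ratio test: strict `d₁/d₂ < τ`, τ = 0.8. Duplicate target descriptors
  (d₂ = 0) are rejected as ambiguous; a one-element target set admits no
  ratio and yields no matches.
* Symmetry: a pair survives only if best-in-both-directions.
* Patch correlation: Gaussian-weighted Pearson correlation over the cubic
  window of half-width d = 5 voxels (Chebyshev ball; spherical masking is a
  switch), weights σ = d/2 applied symmetrically to mean-removed intensities.
  Patches at the volume border are cropped to their common valid offsets.
  Zero-variance patches give CC = 0: a featureless patch is no evidence of
  correspondence, so it fails any positive threshold. Default threshold 0.7
  (config-exposed; no published value exists for this stage).
* Structural invariance: for pair (a, b), the K = 8 nearest *matched*
  template points around a and target points around b are collected (world
  distance, among the pairs surviving the CC stage, excluding the tested
  pair); the pair is retained iff more than K/2 of those neighbour pairs
  coincide. All pairs are judged against the same pre-filter set in a single
  pass, making the result independent of evaluation order; iterative
  re-evaluation to a fixed point is a flag. K truncates when fewer pairs
  survive.

Stage counts are conserved by construction:
`candidates = removed_by_cc + removed_by_structure + retained`, where
candidates are the pairs entering verification (after symmetric matching).

## Thin-plate spline

3D biharmonic kernel U(r) = r (the 2D r²·log r form does not apply to
volumes). The bordered system `[[K + λI, P], [Pᵀ, 0]]` is solved densely —
N is a few hundred at most. λ = 0 (exact interpolation) by default;
λ > 0 available for noisy landmarks. P must have full column rank 4
(≥ 4 non-coplanar sources), else a descriptive error is raised. Side
conditions Σw = 0, Σw·xᵀ = 0 hold by construction and are asserted in tests.

Direction convention: the spline is fitted with **target-space** keypoints as
sources mapping onto template-space partners, so warping the template onto
the target grid is a single backward resample with no field inversion.
Out-of-volume samples get the template's minimum intensity (air) —
configurable; boundary voxels of an identity map stay exact via an ε
tolerance before the fill is applied.

## Evaluation

SSD is the **mean** squared per-voxel difference (a sum would scale with
grid size; only before/after comparisons on the same grid are meaningful,
so the convention just needs fixing). CC is the plain Pearson correlation of
voxel intensities. When a lung mask is configured, the pipeline scores both
metrics **inside the target-grid mask**: outside the control hull the TPS is
pure extrapolation and the uniform body background carries no registration
signal, so whole-volume scores would mostly measure extrapolation artifacts.
Landmark errors are per-axis Δ with MAD = mean |Δ| and SD (N−1 denominator).
Landmark evaluation runs in template space: a target landmark x is mapped
through the fitted spline f and compared with its template partner q —
before: |x − q| (identity), after: |f(x) − q|.

## Synthetic phantom

The generator states one fixed world: a 96³ grid at 1 mm isotropic spacing;
lung intensity 100, body 600, vessels 500 (bright against the lung, darker
than body, so a single 0–550 intensity band isolates lung + vessels); a
two-generation vessel tree of 2 mm-radius cylinders whose five interior
nodes (degree ≥ 3) are the ground-truth bifurcation landmarks. Junctions
carry a 1.5× radius bulge — real vascular junctions are thickened, and the
bulge keeps the corner response centred on the node coordinate. The volume
is smoothed by a 0.8-voxel Gaussian (partial-volume band-limiting) and
additive white Gaussian noise (σ = 1, mild relative to the 400-unit
lung/vessel contrast) is drawn from the stated seed.

The deformation field maps target to template as x ↦ x + u(x), with u a
global translation (0.5, 0.8, 2.0) mm plus two compact Gaussian bumps with
z-dominant amplitudes (peak displacement ≈ 9 mm over the lung, under the
10 mm design bound; z dominance mimics diaphragm-driven motion). The target
phase is rendered by one trilinear resample, so ground truth is exact by
construction; landmark positions in the target solve x + u(x) = node by
fixed-point iteration (contractive at these amplitudes). Displacements above
25 % of the grid extent are refused.

Not emulated: airway/lobe anatomy, CT noise texture and HU calibration,
intensity change between phases, and pleural sliding. A green end-to-end
test therefore establishes that the pipeline recovers a *smooth, invertible,
modest* deformation from correct tissue-feature correspondences — not
performance on clinical CT.

## Numerical choices and degenerate inputs

* Response ties broken lexicographically by voxel index — determinism.
* Gradient/window kernels truncated at 4σ and 3σ respectively.
* eigvalsh (symmetric solver) for all eigenvalue work.
* TPS rank test tolerance scales with the coordinate magnitude.
* Empty masks, empty keypoint sets and empty match lists flow through as
  empty results with zeroed reports, not errors; fewer than 4 retained
  matches falls back to an identity warp with a warning.
* The pipeline is deterministic given inputs and config; only phantom noise
  and decoy placement consume the seed.

## Known limitations

* No scale-space detection or rotation invariance: large rotations or
  scale changes between phases will break descriptor matching.
* λ = 0 TPS interpolates keypoint quantisation error (~half a voxel)
  exactly; with very few matches this can locally over-bend the field.
* The CC threshold (0.7) and structural parameters (K = 8, K/2) have no
  published reference values; they are exposed in the config and logged.
* Whole-volume SSD can worsen after registration when controls cover only
  the lung — by design the masked metric is the meaningful one.
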
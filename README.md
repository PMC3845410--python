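# lungreg

Feature-based nonrigid registration for lung CT volumes.

Respiratory motion deforms the lungs nonlinearly between breathing phases, which
makes rigid alignment useless for tasks such as tumour targeting in image-guided
radiotherapy. `lungreg` registers two CT phases by matching *tissue* features —
vessel bifurcations, vascular endpoints, boundary corners — rather than the blob
features a scale-space detector favours, and interpolates the recovered sparse
correspondences with a thin-plate spline.

## Method

Given a template volume *I*₁ (moving) and target *I*₂ (fixed), both resampled to
isotropic spacing:

1. **Tissue-feature detection.** At every voxel the 3×3 structure tensor
   *M* = Σ *W*·∇*I* ∇*I*ᵀ is formed from Gaussian-derivative gradients
   (Iₓ, I_y, I_z) summed under a Gaussian window *W*. Corners are voxels where
   *all three* eigenvalues λ₁ ≥ λ₂ ≥ λ₃ of *M* are large; the detector response
   is λ₃ (Shi–Tomasi style). Keypoints are 26-neighbourhood response maxima,
   greedily thinned so all pairwise distances exceed a minimum (default 5 mm).
2. **3D SIFT description.** Each keypoint's 16×16×16 neighbourhood is split into
   4×4×4 subregions; each subregion accumulates an 8×4 histogram of gradient
   (azimuth, elevation) in 45° bins, magnitude- and Gaussian-weighted:
   64 × 32 = **2048** components, L2-normalised.
3. **Match verification cascade.** Nearest-neighbour matching with Lowe's ratio
   test (d₁/d₂ < τ = 0.8), kept only if mutual (template→target and
   target→template); then a Gaussian-weighted Pearson correlation of the
   intensity patches within *d* = 5 voxels of the two endpoints must exceed a
   threshold; finally a *structural invariance* consensus: the K matched
   neighbours of a true pair's endpoints must largely correspond, since the
   relative layout of lung structures is preserved across the breathing cycle.
4. **Thin-plate-spline warp.** A 3D TPS (kernel U(r) = r) is fitted with the
   retained target keypoints as sources mapping onto their template partners,
   so the template is backward-warped onto the target grid in one resample.

Quality is reported as mean squared intensity difference (SSD), intensity
Pearson correlation (CC), and per-axis landmark error summaries (MAD/SD in mm).

## Worked example

A built-in phantom generator renders a dark ellipsoidal lung with a bright
branching vessel tree and deforms it by a known smooth displacement field
(≤ 10 mm, dominantly superior–inferior). Registering the two phases:

```bash
lungreg phantom --out phantom/ --shape 96 --seed 1
lungreg register phantom/template.mha phantom/target.mha --out run/ \
    --set mask_lo=0 --set mask_hi=550 \
    --landmarks-template phantom/landmarks_template.txt \
    --landmarks-target phantom/landmarks_target.txt
```

prints (equivalently via the library, `lungreg.register(...)`):

```json
{
  "match_report": {"candidates": 17, "removed_by_cc": 0,
                   "removed_by_structure": 0, "retained": 17},
  "ssd_before": 13414.34, "ssd_after": 3034.67,
  "cc_before": 0.605, "cc_after": 0.876,
  "landmark_mean_error_before_mm": 7.10,
  "landmark_mean_error_after_mm": 0.75
}
```

All 17 verified correspondences are true matches on this clean phantom, so the
cascade removes nothing; SSD over the lung drops ~4.4×, intensity correlation
rises from 0.61 to 0.88, and the mean error at the five ground-truth vessel
bifurcations falls from 7.1 mm to 0.75 mm (an 89 % reduction). Stage counts,
match tables, the fitted spline and metrics are written to `run/`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

regenerates the default 96³ phantom pair with the given seed, runs the complete
detection → description → matching → TPS pipeline on it, and prints the match
report, before/after SSD and CC, and the landmark error summaries computed in
that run.
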
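# ldpo — gray/white-matter boundary width mapping

`ldpo` quantifies the **blurred gray/white-matter junction**, a hallmark of
focal cortical dysplasia (FCD) on T1-weighted MRI, by measuring the physical
width (in mm) of the gray/white boundary (GWB) at every junction voxel. A
blurred junction is a *broadened* junction: where a healthy cortex shows a
sharp intensity step from gray matter (GM) to white matter (WM), an FCD
lesion shows a gradual intensity ramp occupying a wider band of tissue. The
package is aimed at researchers building MRI feature maps for lesion
detection and at anyone needing a Laplace-equation thickness estimator on a
voxel grid.

## Method

Given a skull-stripped, bias-corrected T1 volume `Y`, the pipeline runs four
stages:

1. **HMRF-EM segmentation.** Tissue intensities are modelled as Gaussians
   G(y; μ_l, σ_l) for l ∈ {CSF, GM, WM} with μ_CSF < μ_GM < μ_WM, coupled to
   a Potts spatial prior over 6-connected pairs with clique potential
   V_c = ½·β·(1 − 𝟙[x_i = x_j]). MAP labels are estimated by raster-order
   ICM; (μ_l, σ_l) are re-estimated as posterior-weighted moments until the
   parameter change falls below tolerance. The output is one posterior
   probability image per tissue, normalized so p_CSF + p_GM + p_WM = 1 at
   every brain voxel.
2. **Boundary labeling.** A voxel is GWB when neither GM nor WM dominates:
   0 < p_GM < T_prob and 0 < p_WM < T_prob, with T_prob = 0.9; voxels with
   p_GM ≥ T_prob (resp. p_WM ≥ T_prob) are GM (resp. WM).
3. **Potential field.** The GWB band is treated as the gap of a capacitor:
   ψ = 50 on GM, ψ = 150 on WM (Dirichlet), ψ = 100 initially inside the
   band, relaxed by synchronous Jacobi sweeps (six-face-neighbour means)
   until the relative change of the total field energy
   ε = Σ‖∇ψ‖ over band voxels drops below 10⁻⁵.
4. **Path tracing and width.** From every GWB voxel the field is descended
   (always stepping to the 26-neighbour with smallest ψ) until a GM voxel
   and ascended (largest ψ) until a WM voxel. The width D(v) is the world-mm
   distance between the two endpoints; anisotropic voxel spacing is honoured
   through the affine. Large D flags a broadened, blurred junction.

A classical comparator is included: the gradient-magnitude map (least-squares
first derivative in a 5×5×5 window, small values = blurred junction), plus a
voxelwise evaluation module (threshold sweeps, ROC, precision/recall,
F-score) and a phantom generator with exact ground truth.

## Worked example

`examples/03_lesion_detection_f_score.py` builds a 48×48×24 slab phantom
whose GM/WM ramp is 3 mm thick, except inside a 12 mm-radius "lesion" where
it is doubled to 6 mm, then measures widths from the phantom's exact
partial-volume probabilities and sweeps the width map against the lesion
mask:

```
lesion mean width   : 5.75 mm (true band 6 mm)
surround mean width : 4.78 mm (true band 3 mm)
best F-score 0.668 at threshold 4.91 mm (between the two generating thicknesses)
```

The two width populations straddle their generating thicknesses (the
measured value is endpoint-to-endpoint, one voxel beyond the band on each
side, and greedy 26-neighbour stepping quantizes to diagonal distances), and
the optimal detection threshold falls between the normal and lesional
thickness — the behaviour that makes the map usable as a lesion feature.

Command-line use on a NIfTI volume:

```sh
ldpo run --input t1.nii.gz --out results/ --t-prob 0.9 --width-mode endpoint
ldpo phantom make --out phantom_dir/
ldpo feature gradient --input t1.nii.gz --out grad.nii.gz --window 5
ldpo evaluate --feature results/gwb_width.nii.gz --truth lesion.nii.gz \
    --polarity high_is_positive --out curve.csv
```

`ldpo run` writes the width map, a per-voxel trace-status map, summary
statistics and a provenance record capturing every parameter and seed;
reruns with the same configuration are byte-identical.

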
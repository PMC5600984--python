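# Methods

This note documents the models, numerical choices and known limitations of
the `ldpo` package. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Problem and model

The gray/white boundary (GWB) is the transition band between cortical gray
matter and subcortical white matter. On T1-weighted MRI a healthy junction
is a near-step intensity change spread over roughly a voxel by the partial
volume effect; in focal cortical dysplasia the junction can blur into a
gradual ramp several millimetres wide. The package turns that qualitative
blur into a per-voxel width in millimetres.

### Tissue segmentation (HMRF-EM)

Intensities are modelled per tissue l ∈ {CSF, GM, WM} as Gaussians
G(y; μ_l, σ_l); the T1 ordering μ_CSF < μ_GM < μ_WM is enforced by sorting
the components after every M-step. Spatial coherence comes from a Potts
prior on 6-connected voxel pairs with clique potential ½·β·(1 − 𝟙[equal]).

* **MAP estimation** uses iterated conditional modes in fixed raster order
  (a sequential update; implemented as a numba kernel). Ties in the
  per-voxel arg-min go to the lowest label index. Each sweep can only lower
  the joint energy, which the test suite asserts.
* **E/M steps.** Tissue posteriors are computed per voxel as
  p_l ∝ G(y; θ_l)·exp(−β·U_l), where U_l counts label disagreements with
  the current 6-neighbour labels, normalized over the three labels so they
  sum to one (the normalizer printed in the source formulation would make
  the prior identically one; per-voxel normalization is the reading that
  yields usable probabilities). Parameters are posterior-weighted moments.
* **Initialization** is k-means (k = 3) on the in-mask intensities with a
  fixed seed; **convergence** is declared when max |Δμ_l|, |Δσ_l| < 1e-4
  (default), capped at 30 EM rounds of up to 10 ICM sweeps.
* **β** defaults to 1.0. Larger β suppresses isolated misclassified voxels
  but also *sharpens* the posterior transition at tissue interfaces (see
  Limitations); with β = 0 the fit reduces exactly to an equal-weight
  Gaussian-mixture EM, which the tests cross-check against an independent
  mixture fit (means agree to 1e-3 on phantoms).

### Boundary labeling

A voxel is GWB when both 0 < p_GM < T_prob and 0 < p_WM < T_prob;
p_GM ≥ T_prob claims GM, p_WM ≥ T_prob claims WM (precedence GM, WM, GWB);
everything else is background. T_prob = 0.9. The strict-positivity clauses
are honoured exactly. Note that under a three-class Gaussian posterior the
CSF plateau satisfies the GWB clause (both probabilities are positive but
tiny), so CSF regions enter the band; such voxels cannot reach WM during
tracing, receive a failure status and zero width, and therefore never enter
width statistics. CSF probability itself does not participate in the rule.

### Potential field

The band is the gap of a parallel-plate capacitor: ψ = 50 on GM and ψ = 150
on WM are Dirichlet boundaries (any constants with ψ_GM < ψ_GWB < ψ_WM
work; 50/100/150 are the defaults), the band starts at 100 and is relaxed
with synchronous Jacobi sweeps — each band voxel becomes the mean of its
six face neighbours' previous values, so the result is independent of
visitation order. Where a neighbour has no potential (CSF, background,
volume edge) a mirror (zero-flux) condition substitutes the centre's own
value, which confines the potential drop to the GM→WM direction rather than
leaking toward CSF.

The stopping quantity is the total field energy ε_t = Σ band ‖∇ψ‖ with
central differences (one-sided where only one neighbour is in-field).
Iteration stops when |ε_{t+1} − ε_t| / ε_t < 1e-5 (default) or at 2000
sweeps. Two numerical points:

* ε_0 is the energy of the *initialized* field, so the relative-change test
  is defined from the first sweep on and a degenerate zero energy is
  guarded.
* The absolute value matters: starting from a flat interior the summed
  gradient magnitude *grows* monotonically toward the harmonic profile
  (58.3 → 75.0 on the three-voxel column fixture), so a signed test would
  either never fire or fire immediately depending on the approach
  direction.

Accuracy: the solver matches the closed-form harmonic solution on 1-D
columns to < 1e-3 and a direct sparse solve of the identical stencil on
random ≤ 500-voxel regions to < 1e-3 (both asserted in the tests).

### Path tracing and width

From each band voxel a greedy walk steps to the neighbour with the smallest
ψ until a GM-labelled voxel is reached, and symmetrically to the largest ψ
until WM. The search window is the 26-neighbourhood by default
(6-neighbourhood available). Stopping tests the *label*, not floating-point
equality with the boundary constants. Design points:

* **Tie-breaking.** Among equal-ψ neighbours the smallest step wins (face
  before edge before corner), then lexicographic offset order. On an
  exactly planar field the nine next-plane neighbours tie; a purely
  lexicographic rule would always pick a corner, drifting every path
  diagonally and inflating slab widths beyond their geometric value (7.15 mm
  measured for a 5 mm slab), while smallest-step-first keeps paths
  axis-aligned and recovers w + 1 mm exactly. When a genuine lateral field
  tilt exists (e.g. near a lesion) the walk legitimately steps diagonally —
  value-steepest descent over a window is the method's defining rule — so
  widths quantize to diagonal distances there.
* **Termination.** A step requires a strictly better neighbour; on a
  plateau the trace stops with status `gm_unreachable`/`wm_unreachable`.
  Strict monotonicity makes revisits impossible, but a visited-set guard
  still maps any revisit to `cycle_detected`, and a step cap (default: sum
  of the volume dimensions) bounds every walk. Per-voxel failures are
  recorded in a status map, never raised.
* **Width.** `endpoint` mode (default) reports the world-mm distance
  between the GM and WM endpoints — the mean of the defining distance pair,
  which share endpoints. `halfpath-mean` averages the two origin-to-endpoint
  half distances and can produce sub-voxel widths (the variant consistent
  with reported sub-voxel minima in the source material); both are exposed
  because the original convention is ambiguous. Distances go through the
  affine, so anisotropic spacing such as 0.8594 × 0.8594 × 0.9 mm is exact.
  Widths are 0 outside successfully traced band voxels.

On slab phantoms the measured width of a w mm band is w + 1 mm (endpoints
sit one voxel inside each tissue); the series w ∈ {2, 3, 5, 8} mm returns
means {3, 4, 6, 9} mm, strictly increasing. A slab rotated 45° in-plane
yields a mean within 6% of the axis-aligned value (asserted at 15%).

### Gradient comparator

The gradient map estimates the first derivative by an unweighted
least-squares plane fit over a 5×5×5 window; for a full centred cuboid the
normal equations diagonalize and the fit becomes a separable ramp-kernel
correlation, making the estimator isotropic and cheap. Derivatives are per
mm. Edge voxels use the largest centred window that fits (minimum 3; the
outermost layer uses a reflected window-3 estimate). Polarity is
low-is-positive and feature values below 5 are excluded from evaluation as
image background. Interior values match per-voxel normal-equation fits to
1e-6.

### Evaluation

Threshold sweeps run over 256 evenly spaced values between the in-mask
minimum and maximum feature value. Positives are value > T for
high-is-positive features and value < T for low-is-positive ones. The 0/0
conventions are fixed: precision, recall and F are 0 when their denominator
is 0. Evaluation can be restricted to an arbitrary mask; a seeded helper
selects random lesion-containing slices for slice-based protocols. Tied
best-F thresholds resolve to the smallest.

## Phantoms: what they emulate and what they do not

The generator produces slab and spherical-shell geometries with three
Gaussian tissue classes (CSF < GM < WM), a linear (optionally smoothstep)
partial-volume ramp of controllable physical width at the GM/WM interface,
anisotropic spacing, and an optional lesion where the band is locally
thickened by a multiplier > 1 (the lesion keeps the GM-side edge fixed, so
a multiplier-2 lesion over a 3-voxel band produces exactly 6 ramp voxels).
Bundles carry ground-truth labels, the generating width per band voxel, the
lesion mask, and exact partial-volume fraction maps pv_gm/pv_wm
(probability read as tissue proportion per voxel). The ramp is anchored at
a half-voxel offset so an integer-width band contains exactly that many
strictly intermediate voxels.

Default study conditions, chosen once: tissue means (50, 110, 170) with
σ = 10 (the three-class recovery setting); the full-pipeline lesion
experiment uses σ = 15, i.e. a WM–GM contrast-to-noise of 4, with
multiplier 2 and a 3 mm base band. Noise is additive i.i.d. Gaussian per
class; Rician bias, spatially correlated noise (scanner PSF), bias fields
and cortical folding are *not* emulated. Passing phantom tests therefore
demonstrates correctness of the measurement chain on known geometry, not
clinical performance on real anatomy.

## Calibration of the full pipeline (a real limitation)

When the band is obtained from HMRF-EM posteriors, a voxel is labelled GWB
only where the Gaussian likelihood ratio is within the T_prob bounds — an
intensity window of about 2σ²·ln9 / Δμ around the class midpoint. On a ramp
of width w this corresponds to roughly w·ln9·(σ/Δμ)² voxels, which at a
contrast-to-noise of 4 is only ~27% of the ramp, and the MRF prior sharpens
the transition further. The segmented band is therefore systematically
thinner than the geometric ramp, and i.i.d. voxel noise makes it patchy, so
full-pipeline widths measure the *posterior-ambiguity* width, which scales
with — but is smaller than — the anatomical blur. Consequences, all
reproduced by `scripts/acceptance.py`:

* end-to-end lesion contrast exists and is ordered (lesion mean
  1.55 mm > surround 1.50 mm at the default conditions) but is far smaller
  than the generating 2× contrast;
* geometric width recovery ([w, w+2] mm) is validated on the ground-truth
  band, and threshold separation (best-F threshold 4.91 mm between the 3 mm
  surround and 6 mm lesion thicknesses, F = 0.67) on the exact
  partial-volume probabilities, where the probability images mean what the
  width model assumes they mean.

On real, spatially smooth MR data with lower tissue contrast-to-noise the
ambiguity band is wider and more coherent, which is the regime the method
was designed for.

## Other known limitations

* The literal labeling rule admits CSF into the band (handled via trace
  statuses, see above); no CSF-probability ceiling is applied.
* Greedy descent over a window follows the steepest *value*, not the
  steepest direction, so paths quantize to diagonals under lateral field
  tilt; sub-voxel streamline integration of ∇ψ is out of scope.
* Jacobi relaxation is unaccelerated (no SOR/multigrid); fine for band-like
  domains whose diameter is the band thickness.
* The pipeline assumes skull-stripped, bias-corrected input; brain
  extraction, registration and histogram normalization are external.
  The working intensity normalization is a global min–max rescale to
  [0, 255].
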
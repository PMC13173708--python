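# Methods

`arcdose` implements a desk-scale, fully self-contained analogue of an
end-to-end VMAT auto-planning workflow: directional beam-band priors,
a two-stage cascaded 3D dose-prediction model trained with a composite
DVH-aware objective, a DVH-driven iterative inverse planner running
against a surrogate dose engine, and a dose/DVH/gamma evaluation stack.
This note records the models, the defaults and why they are set as they
are, and what the synthetic setting can and cannot demonstrate.

## Synthetic pelvic phantoms (the data model)

Clinical cohorts and a commercial treatment planning system are not
part of this package; every experiment runs on generated cases. A case
consists of a CT-like volume, nine binary structure masks (PTV,
bladder, rectum, small intestine, spinal cord, marrow, both femoral
heads, body), and a reference dose.

Geometry: an elliptical body per axial slice with a mild
superior–inferior taper; an ellipsoidal PTV near the axial center;
bladder anterior and rectum posterior, abutting the PTV; a thin
posterior-midline spinal-cord column; lateral femoral-head spheres; a
bony pelvic-ring annulus that doubles as the marrow mask (no separate
marrow geometry is modelled); a few superior/anterior small-intestine
blobs. Organ centers and sizes are jittered uniformly (defaults:
position ±4 % of the axis length, size ±10 %), so with jitter set to
zero the geometry is seed-independent by construction. CT values are
−1000 HU outside the body, ~0 HU soft tissue, 700 HU bone, with
additive Gaussian noise (σ = 20 HU) inside the body.

Defaults: grid 64×64×32 voxels at (2.5, 2.5, 5.0) mm — 5-mm slices and
an in-plane resolution near a 3-mm dose grid; prescription 45 Gy. The
test suite and the acceptance script run a 32×32×16 sub-scale grid at
the same spacing (a smaller field of view) so that the whole pipeline,
including repeated network training, fits comfortably on one CPU; this
problem size is the package's deliberate desk-scale choice and is noted
wherever results are produced.

Reference dose: a parallel-ray exponential-attenuation engine.  For a
gantry angle θ (axial plane, taken mod 180° since opposed parallel
beams coincide), unit-fluence rays deposit `exp(−μ·depth)` inside the
body, with `depth` the path length inside the body and μ = 0.004 mm⁻¹
(megavoltage-like).  Dose is exactly linear in the per-angle weights
and in optional per-ray (slice × lateral) beamlet weights.  Eight
equispaced angles (22.5° apart over 0–180°) are the default beam
arrangement.  The reference plan for each case is produced by the
package's own inverse optimizer under a fixed clinical-style protocol
(PTV uniformity at prescription, D98% ≥ 97 % of prescription, hot-spot
caps, organ mean/max goals) and renormalized so PTV Dmean equals the
prescription.  Non-convergence of the optimizer is flagged in the case
metadata, never silent.

Angle convention: 0° rays travel along the image column axis, 90° along
the row axis; the beam-band construction uses the same convention so
bands align with the dose corridors the engine produces.  For the
default four-direction set {0°, 45°, 90°, 135°} the band set is
identical under either of the two natural axis conventions.

What the phantom does *not* emulate: realistic CT texture and
heterogeneity corrections, divergent beams, MLC sequencing, and the
anatomical variability of a real cohort.  Tests passing here show the
machinery is correct and the learning/planning loops behave as
designed; they do not certify clinical-scale accuracy.

## Beam-band masks

On each axial slice, the band for angle θ is the corridor between the
two lines parallel to the beam direction and tangent to the PTV:
pixels whose center projects, along the band normal, into the closed
interval spanned by the PTV pixel-center projections.  Pixel-center
inclusion with a closed interval gives reproducible discrete tangency
(shrinking the interval by one pixel on either side always excludes at
least one PTV pixel).  k directions are spaced `i·180/k`; k = 4 yields
0/45/90/135.  Bands are built per slice and stacked — no 3-D tilting —
and empty PTV slices give empty bands.  Clipping bands to the body is
available but off by default.

The band-count sweep uses *nested* angle subsets (prefixes of a
bit-reversal ordering of the finest set, which reproduce the uniform
spacing at powers of two), so the band-union dose coverage — the
fraction of above-threshold dose mass inside the union, threshold 50 %
of the maximum by default — is monotone in k by construction.

## Two-stage dose prediction

Stage 1: a 3D U-Net (encoder–decoder with skip connections; default
depth 3, base width 16; the suite uses depth 2, width 8) maps 10 input
channels — CT normalized to [0, 1] from a [−1000, 1000] HU clip, plus
the nine masks — to a non-negative coarse dose (softplus output) in
prescription-normalized units.  It is trained with body-masked MAE
(Adam, learning rate 3·10⁻⁴, batch of one whole volume, best-validation
checkpointing).  The learning rate is deliberately small: larger rates
(≥10⁻³) can drive the softplus output into saturation at exactly zero,
from which MAE gradients cannot recover.

Stage 2: a residual U-Net sees 15 channels — the 10 above, the coarse
dose, and the four band masks — and predicts a *correction*; the
refined dose is `max(coarse + correction, 0)`.  The output convolution
is zero-initialized so the cascade starts exactly at the coarse dose.
Stage 1 stays frozen; band masks are computed once per case.

The networks and their backpropagation are implemented directly in
numpy (im2col-free offset-GEMM convolutions); training is
single-threaded and deterministic given the seed.

## Composite refinement objective

On prescription-normalized dose,

L_total = λ_body·L_body + λ_band·L_band + λ_grad·L_grad + λ_dvh·L_dvh

* **L_body** — MAE over body voxels (global accuracy).
* **L_band** — MAE over the band union (entrance-corridor fidelity).
  The union (not per-band averaging) is used.
* **L_grad** — mean L1 difference of spacing-aware central-difference
  gradient *vectors* (not magnitudes) inside the band union, in
  normalized dose per mm (fall-off consistency).
* **L_dvh** — L1 distance between soft cumulative DVHs: per ROI,
  `s(b) = mean_v σ((d_v − b)/T)` on a fixed bin grid (25 bins over
  0–120 % of prescription), averaged over ROIs and bins.  Temperature
  T = 0.02 normalized ≈ 0.9 Gy of softness; as T → 0 the hard DVH is
  recovered.  Smooth in the prediction and gradient-checked.

Every term is non-negative, zero on identical inputs, and ships with an
analytic gradient verified against finite differences (1e-4 relative).

Default weights are λ = (1, 0.25, 0.25, 0.25).  The auxiliary terms
have intrinsically larger per-voxel gradients than the global MAE — the
band term averages over a smaller region, and the soft-DVH term is
sharpened by 1/T inside small ROIs — so equal weighting lets them
dominate the global objective; quarter weights keep each auxiliary
subordinate while still shaping band regions, gradients, and endpoints.
All weights, the temperature, and the bin grid are configurable.

## Auto-planning loop

1. Extract goal endpoints **M0** from the refined predicted dose (one
   row per (ROI, metric) of the planning spec; the default spec uses
   only metrics that translate into objectives: PTV Dmean/D98%/D2%/V95%
   and organ mean/max/DVH-point metrics).
2. Assemble one objective per M0 row, goals equal to the M0 values:
   PTV coverage metrics become lower bounds, PTV hot-spot metrics and
   all organ metrics upper bounds, PTV Dmean a two-sided uniformity
   goal.  Default weights favour target objectives over organ ones.
3. Optimize non-negative beamlet weights by projected gradient descent
   with a backtracking line search on a weighted sum of one-sided
   quadratic penalties (DVH-point objectives use a sigmoid-soft volume
   count, τ = 0.75 Gy).  The optimizer is deterministic: zero (or
   warm-started) initial weights and a fixed iteration budget.
4. Evaluate the achieved endpoints **Mc**; a metric is met when its
   normalized shortfall against M0 is ≤ 0.005 (≈ 0.23 Gy or 0.5 volume
   points at 45 Gy).  Unmet upper-bound goals are multiplied by 0.98,
   unmet lower-bound goals by 1.02 — the 2 % step is applied to the
   *dose goal*, and only to unmet objectives — followed by
   re-optimization (warm-started).  At most five iterations; the loop
   stops early when everything is met.
5. The retained plan minimizes the aggregate violation — the sum of
   positive shortfalls divided by the prescription (dose metrics) or
   100 points (volume metrics) — with ties going to the earliest
   iteration.

## Evaluation stack

* **DVH** — exact voxel-counting cumulative histogram (0.1 Gy bins for
  curves); endpoints are computed on the *unbinned* voxel sample:
  D{p}% by linear interpolation of the empirical quantile, Dmax as the
  single hottest voxel (the grid is too coarse for D0.1cc), HI as
  (D2% − D98%)/D50%, CI as the Paddick index at the prescription
  isodose (RTOG ratio available).
* **Dose score** — body-restricted mean absolute voxel difference (Gy).
* **DVH score** — mean absolute endpoint difference over a spec;
  default PTV {D2%, D98%, Dmean} plus every organ {Dmean, Dmax}; an
  OpenKBP-style spec and a protocol-style spec (with V-metrics) are
  provided by name.
* **snDVH score** — each endpoint difference divided by its scale
  (prescription for dose metrics, 100 points for volume metrics) and
  averaged, making Gy and % endpoints commensurate.  The exact
  normalization of its clinical namesake is not published; this
  definition is the package's documented surrogate.
* **Gamma** — global normalization (dose criterion as % of the
  reference maximum), evaluated at reference voxels above 10 % of the
  reference maximum; the search scans displacements on a 3× refined
  voxel grid within a radius of 3× the distance criterion, with the
  evaluated dose trilinearly interpolated.  The reference fixes the
  normalization, so the statistic is deliberately not symmetric under
  swapping the doses.  The implementation is cross-checked in the test
  suite against an independent per-voxel brute-force implementation.

## Numerical choices and degenerate inputs

Empty PTV slices produce empty bands; empty ROIs raise (scores) or are
skipped with a warning (DVH loss).  Network grids must be divisible by
2^depth, enforced with an actionable error.  Volumes are written as
gzipped NIfTI with a fixed gzip timestamp so identical cases are
bitwise-identical on disk.  All randomness flows from explicit seeds;
training, optimization, and the full pipeline are reproducible
end-to-end (the end-to-end test runs the pipeline twice and compares
reports for equality).

## Known limitations

* The loss-term ablation (cumulative arms baseline → +L_band → +L_grad
  → +L_dvh) is evaluated at desk scale on a 10-case cohort, which
  leaves a single test case under the 8:1:1 split.  The arm-to-arm
  differences in the test dose score (a few hundredths of a Gy on a
  ~2 Gy score) are comparable to the published relative effects but
  smaller than the single-case sampling noise, so the monotone-ordering
  property is not reliably resolvable at this scale; the corresponding
  acceptance test documents this by failing honestly rather than being
  weakened.  The stage-1 learning property and the cascade
  "refinement never harms" guard are robust and pass.
* The surrogate dose engine is parallel-ray with scalar attenuation; it
  reproduces directional corridors but not scatter, divergence, or
  deliverability constraints, so planner results demonstrate the loop's
  contract, not machine-deliverable plans.
* Marrow shares the bony-shell mask; DVH metrics for it are therefore
  correlated with the femoral-head bone compartment in CT but not in
  geometry.
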
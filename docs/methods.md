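# Methods

This note documents the models, numerical choices and synthetic-data design
behind `plaque-ifem`, and what the shipped tests do and do not demonstrate.

## Constitutive models and post-processing

Tissue components are isotropic, incompressible and hyperelastic with
strain energies depending on the first invariant only:
Neo-Hookean `W = c1 (I1 − 3)` for the lipid pool (c1 = 1 kPa) and
calcifications (c1 = 1 GPa = 10⁶ kPa), Yeoh
`W = Σ_{i=1..3} cᵢ (I1 − 3)ⁱ` for the fibrous intima and the wall
(media + adventitia). All constants are kPa; lengths are mm; pressures enter
in mmHg and are converted once (1 mmHg = 0.1333224 kPa).

A Yeoh triplet is screened with the stability criteria
`c1 > 0`, `c3 > 0`, `c2 > −3 c1 c3` (strict inequalities — boundary values
count as unstable). Note the criteria do not guarantee a monotone uniaxial
response everywhere: for strongly negative `c2` the tangent `dW/dI1` can dip
negative over a strain interval, and the forward solver then legitimately
fails to find an equilibrium (the optimizer receives a penalty).

For cross-study comparison the uniaxial incompressible Cauchy stress is
`σ(λ) = 2 (λ² − 1/λ) dW/dI1` with `I1 = λ² + 2/λ`; this closed form is
verified in the tests against a finite-difference derivative of `W` along
the uniaxial path (`σ = λ dŴ/dλ`, relative agreement < 10⁻⁶).

Medians of fitted constants (reported per layer) use the midpoint-of-central-
order-statistics convention and are returned at full precision: medians of a
table printed to two decimals can land exactly on a rounding tie, so
comparisons with published medians are only meaningful to half a printed
unit.

## Forward model

Plane strain (unit out-of-plane stretch, included in `I1 = tr(FFᵀ) + 1`)
with exact incompressibility enforced by a mixed displacement–pressure
formulation: bilinear quadrilaterals (2×2 Gauss) with one pressure unknown
per element constraining the element-mean of `det F` — the open analog of
commercial "hybrid" plane-strain elements. The first Piola-Kirchhoff stress
is `P = 2 W′(I1) F − p cof F`; a stress-free reference requires
`p = 2 W′(3)`, which is how the hydrostatic field is initialized.

The intraluminal pressure is a follower load on the deformed lumen boundary
(consistent nodal forces and tangent). The outer boundary is traction-free.
Rigid-body modes are removed by pinning three displacement components (a
sparse gauge — dense average-displacement constraint rows destroy the
sparse factorization); every converged solution is then projected to the
zero-mean-translation/zero-mean-linearized-rotation gauge, which is the
convention used when comparing with tracked displacements. Since an
equilibrium is unique only up to rigid motion, the projection is exact
bookkeeping, not an approximation (the inflation problem carries no net
torque, so the rotation correction is ~0).

Newton's method with an analytic consistent tangent converges quadratically;
load steps adapt (grow 1.5× on success, halve on failure, abort below
10⁻⁴ kPa and report the last converged pressure so the optimizer can
penalize). Convergence: relative residual < 10⁻⁸, ≤ 15 iterations per step,
early abort when the residual grows twice in a row. The reference
configuration is the ~10 mmHg imaging state treated as stress-free, with
the full 80/100/120 mmHg applied to it; an `incremental` option applies
pressure differences instead.

Validation: a semi-analytic oracle for concentric incompressible
plane-strain tubes, `P = ∫ 2 W′(I1)(λθ² − λθ⁻²) R/r² dR` with
`r² = R² + (rᵢ² − Rᵢ²)`, integrated adaptively over the reference radius and
cross-checked against a dense Riemann sum. FE inner-radius displacements
agree with the oracle to < 0.1 % (Neo-Hookean) and < 0.3 % (Yeoh) at a
16×96 annulus mesh. A caveat discovered with the oracle: a plane-strain
incompressible Neo-Hookean tube has a finite limit pressure
(≈ 13.9 kPa for c1 = 10 kPa, Ro/Ri = 2), so soft Neo-Hookean validation
cases are only meaningful below it.

## Synthetic cross-section phantoms

The generator emulates diseased human coronary morphology: an eccentric
circular lumen (radius 0.7 mm, offset 0.3 mm), an intima ring and a wall
ring sized so the component areas match reported averages (fibrous intima
≈ 2.64 mm², wall ≈ 4.61 mm², lipid pool ≈ 1.33 mm²), an optional
calcification, and seeded smooth harmonic perturbations (amplitude
0.02 mm, harmonics 2–5) of the outer contours. Inclusions are tapered polar
crescents whose thickness profile is solved analytically for the target
area; masks are rasterized at pixel centers `(i + 0.5)·pixel_size`
(default 25 µm).

Meshing is structured-transfinite from the lumen centroid: node rings grade
from the lumen contour to the intima-outer contour (a ring coincides with
the intima/wall interface) and on to the wall contour; two rings are snapped
to the inclusion boundaries where the inclusion is at least one element
thick, and elements are tagged by centroid. At the standard 0.035 mm element
size a default phantom meshes to ~7.5k nodes with component areas within
0.6 % of the mask. The lumen is never meshed — it is the pressurized cavity.

What the phantoms do **not** model: MRI/ultrasound segmentation and
registration error (synthetic data are co-registered by construction),
non-star-shaped lumens, layered wall substructure, residual stress, and
longitudinal pre-stretch. Passing recovery tests therefore demonstrate the
estimation machinery, not robustness to real-world geometry error.

## RF speckle simulation

Point scatterers are Poisson-seeded over the tissue labels (default
2000/mm², standard-normal amplitudes) and rendered as a separable
point-spread function: axially a Gaussian-windowed cosine at the two-way RF
spatial period `c/(2 fc)` = 19.25 µm (fc = 40 MHz, c = 1540 m/s; pulse
σ = 12 µm), laterally a Gaussian beam (σ = 60 µm). Default pitches are
2.75 µm axial × 27.5 µm lateral so that the standard tracking window sizes
are (near-)integer sample counts; the axial pitch must satisfy Nyquist for
the RF oscillation. Frames are deterministic given scatterers and the
displacement field (interpolated linearly from FE nodal values); optional
white noise with configurable SNR exercises robustness. Fully developed
speckle shows a Rayleigh envelope (KS-tested). No attenuation, beamforming
artifacts or elevational effects are modeled.

## Displacement tracking

Three fixed passes of zero-mean normalized cross-correlation block matching
(window sizes in µm, converted to the nearest odd sample count; grid
spacings round half-up):

| pass | data | template (µm) | kernel (µm) | grid (µm) | after |
|---|---|---|---|---|---|
| 1 | envelope | 481.3 × 412.5 | 1684.4 × 962.5 | 481.3 × 27.5 | 5×5 median |
| 2 | envelope | 240.6 × 247.5 | 360.9 × 522.5 | 27.1 × 27.5 | 41×41 median |
| 3 | raw RF | 120.3 × 137.5 | 144.4 × 192.5 | 27.1 × 27.5 | subsample peak |

Offsets from each pass seed the next (bilinearly interpolated onto the finer
grid, edge-extended, rounded to integer samples for kernel placement);
kernels are clipped at frame borders and a grid point whose template leaves
the frame is flagged invalid rather than raising. Median filters use reflect
padding with invalid points filled by nearest-neighbor first. The envelope
is the magnitude of the axial analytic signal. Subsample localization fits a
bicubic surface to the 5×5 correlation neighborhood when available; with the
standard windows the correlation map is often only 3 columns wide laterally,
in which case the axes are refined separately (5-point cubic axially,
3-point parabola laterally), with ties broken toward the smaller
displacement. Accumulation across pressure steps follows each grid point's
trajectory, sampling every step's field at the displaced position by
bilinear interpolation; trajectories leaving the valid region are flagged.

Measured accuracy on synthetic speckle (fixed seeds): integer shifts exact,
0.3-sample shifts recovered with ~0.03-sample mean bias and ~0.05-sample
spread, RMSE < 0.1 sample at 20 dB SNR.

## Objective

Axial (beam-direction, +depth) displacements only — lateral estimates are
computed and stored but never enter the cost, mirroring their lower SNR in
practice. Both data sources are averaged inside 100 µm × 100 µm cells; only
cells whose lateral center lies within ±25 % of the tissue's lateral width
around its centroid are kept (the mid-band), each with at least a configured
minimum of FE nodes and valid tracking points (default 3 each; 1 FE node
per cell is appropriate for coarse recovery meshes). With an inclusive
band-edge comparison, a cell whose center lies exactly on the band edge is
kept. Vectors are ordered cell-major with pressures (80/100/120 mmHg)
innermost, and cells losing valid data at any pressure are dropped from both
vectors. `NMSE = Σ(ŷ−y)²/Σ(y−ȳ)²` is reported as a fraction internally and
percent in tables.

## Bayesian optimization and uniqueness

The six constants are searched in
`c1 ∈ [0.1, 50]`, `c2 ∈ [−150, 150]`, `c3 ∈ [0.1, 700]` kPa per layer —
bounds that contain all published fits. `c1` and `c3` use log₁₀ axes:
physiological values (order 0.1–10 kPa) otherwise collapse into a corner of
the normalized box and the GP surrogate stalls (observed directly: the
noiseless self-consistency search plateaued at ~48 % NMSE with linear axes
and reaches < 0.1 % with log axes under the same budget). `c2` is linear and
may be negative; stability is handled by rejecting non-stable candidate
triplets (configurable to penalize instead).

The surrogate is a GP with a Matern-5/2 ARD kernel plus white noise on the
normalized box, fitted to `log(NMSE)` (standardized) by marginal-likelihood
maximization with restarts; observation floor 10⁻¹². Acquisition: expected
improvement on the log scale over a candidate pool of 2048 uniform points
plus perturbations of the incumbent, with every fifth step exploiting the
posterior-median minimum; duplicate proposals are jittered. The search
starts from a seeded Latin hypercube (default 50 points, 400-evaluation
budget, matching the study protocol; the shipped recovery tests use 30/150
to fit a single-CPU time budget) and stops early when the incumbent
improves < 10⁻⁴ over 50 consecutive evaluations. Failed forward solves
receive a 10× worst-observed penalty so the GP stays informative.

Uniqueness: the final GP's posterior-median surface is "inverted" by a
coordinate-wise slice sampler with step-out, drawing uniformly (in the
normalized, log-transformed coordinates) from the sub-level set below
`achieved NMSE + 0.05` — i.e. +5 percentage points, the absolute reading of
the similarity threshold; a relative threshold can be passed instead.
Burn-in 200 sweeps, thinning 5. The report compares per-parameter medians of
the drawn set with the optimizer's best values and flags whether each best
value lies within the drawn interquartile range. A deep-partitioning-tree
candidate structure is *not* reproduced; the contract implemented is
sample-efficient GP-guided global search under a fixed evaluation budget.

## Problem sizes in the shipped experiments

End-to-end recovery runs use a default phantom meshed at 0.12 mm
(~600 elements), frame sequences in 10 mmHg steps at low pressure
(10–80 mmHg, then 100 and 120; small steps keep per-step strain low enough
for the correlation windows where the tissue is most compliant), scatterer
density 2000/mm², and a 150-evaluation budget with 30 initial points —
sizes chosen so the full recovery experiments complete on a single CPU in
minutes while preserving every stage of the pipeline. In the noiseless
self-consistency case the "experimental" vector is the forward model's own
nodal output, so the ground truth attains exactly zero cost; the tracked
case carries realistic speckle-tracking noise (its cost at the true
constants is ~2 % NMSE, a measured bound on the tracking error floor).

Recovered constants at matched NMSE are *not* unique, and the recovery
tests quantify this rather than hide it: even when the noiseless search
matches the displacement data to NMSE ~2×10⁻⁵, the layer-wise uniaxial
responses can still deviate by tens of percent from truth — distinct
(intima, wall) Yeoh pairs produce near-identical mid-band axial
displacement fields at 80/100/120 mmHg. The wall barely strains under
inflation (probed `I1 − 3` of order 0.01–0.05, far below the uniaxial
comparison range), and intima/wall stiffness trades off along a nearly
flat valley of the cost. This is precisely the observation that motivates
the GP-inversion uniqueness report, whose inverted parameter distributions
are correspondingly wide. Recovered uniaxial stress curves are compared to
truth as mean relative error over λ ∈ [1.05, 1.25]; with the achieved
NMSE levels that comparison documents the identifiability limit rather
than a solver deficiency.

## Known limitations

- Quadrilateral Q1/P0 elements only; the mesh generator is
  structured-polar and requires star-shaped component contours.
- No anisotropy (HGO-type fiber models), viscoelasticity, residual stress,
  longitudinal pre-stretch, or 3D effects.
- The speckle simulator is convolutional, not a wave solver; tracking
  performance on real beamformed RF will differ.
- Q1/P0 admits a checkerboard pressure mode on closed structured annuli;
  displacements are unaffected and the element-mean volumetric constraint
  is satisfied to 10⁻¹⁴, but the hydrostatic pressure field should be
  smoothed before interpretation.
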
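# Methods

`radialdce` is a self-contained validation loop for quantitative DCE-MRI
reconstruction: it synthesizes a breast-like dynamic digital reference
object (DRO) with known pharmacokinetics, simulates under-sampled
golden-angle radial multi-coil k-space from it, reconstructs the image
time series with model-based and compressed-sensing solvers, refits the
pharmacokinetic model, and reports bias and precision of the recovered
parameters. Because every stage is simulated, the ground truth is exact
and every error is attributable.

## Digital reference object

The phantom is a 2D slice: an elliptical "breast" of static fibroglandular
tissue (native T1 = 1444 ms, uniform equilibrium magnetization) containing
homogeneous round enhancing lesions (8 mm diameter by default). Each
lesion's concentration-time curve follows the extended Tofts model

    C_t(t) = v_p C_p(t) + K^trans ∫_0^t C_p(τ) exp(-(K^trans/v_e)(t-τ)) dτ

with the transfer constant K^trans swept over
{0.01, 0.04, 0.1, 0.2, 0.3, 0.4, 0.8, 1.2, 1.5} min⁻¹ and fixed
v_e = 0.3, v_p = 0.001. The convolution is evaluated with an exact
exponential integrator for piecewise-linear C_p on a 1 s grid, so the
quadrature error is limited to the linear interpolation of the input
function (verified against a 0.01 s trapezoid oracle at < 1e-8 relative).

The arterial input function is a population shape: a gamma-variate first
pass (whole-blood peak 3 mM, 12 s after bolus arrival) plus a
ramped biexponential recirculation/washout tail, divided by (1 − Hct)
with hematocrit 0.45 to give plasma concentration (peak C_p ≈ 6.2 mM).
The published study cites an external dispersion model without printing
its parameters, so the absolute curve amplitudes here are a documented
package choice; all comparisons are internally consistent because
simulation and fitting share the same AIF. Bolus arrival defaults to
150 s into a 128-frame × 5 s acquisition.

Concentration maps to signal through the spoiled gradient-echo (SPGR)
steady-state equation with TR/TE = 4.7/2.4 ms, flip angle 30°, and
contrast relaxivity r1 = 4.9 mM⁻¹s⁻¹: R1(t) = 1/T10 + r1·C(t),
S = M0 sin α (1−E1)/(1−cos α·E1), E1 = exp(−TR·R1). The support edge of
the breast is anti-aliased over ~1.5 pixels: radial trajectories never
sample the corners of k-space, so a hard-edged object would carry
irrecoverable out-of-band energy that contaminates even the fully-sampled
reference; the smooth edge keeps the static background in-band while the
lesions remain binary disks (their partial-volume edge voxels are part of
what the error statistics measure).

## Acquisition model

Sampling uses 2D golden-angle radial spokes (increment π(√5−1)/2 ≈
111.246°, angles folded modulo π), 8 spokes per 5 s frame against a
fully-sampled reference arm, preserving the study's undersampling factor
R = 704/8 = 88. Readout is 2× oversampled along the spoke (2N samples
spanning |k| ≤ 0.5 cycles/pixel). Coil sensitivities are synthetic:
smooth complex Gaussian lobes centered on a ring around the object with
coil-specific linear phases, normalized to unit root-sum-of-squares —
the properties the reconstruction actually relies on. No physical coil
measurement is modeled.

The encoding operator is a type-2 gridding NUFFT (Kaiser–Bessel kernel,
width 8, 2× oversampled FFT grid, Beatty shape parameter), implemented in
the package and validated against a direct non-uniform DFT at ≤ 1e-6
relative error, with an exact-transpose adjoint. Noise, when requested,
is i.i.d. complex Gaussian per channel with complex standard deviation
equal to 20% of the mean k-space magnitude.

## Reconstruction

Four solvers share the verified operator:

* **Iterative SENSE** (reference arm): per-frame conjugate gradients on
  the density-weighted normal equations of fully-sampled data.
* **PCB** (principal-component basis): the series is constrained to
  s = B c for a rank-K temporal basis B; the spatial coefficients c are
  the CG solution of the projected quadratic problem. Output voxel curves
  lie exactly in span(B).
* **MOCCO** (model consistency condition): minimizes
  ‖W^{1/2}(Es − m)‖² + λ Σ_x ‖((I − BB*)s)_x‖₂ — data consistency plus an
  ℓ1 penalty on the per-voxel temporal-model residual. Grouping the
  residual over time within each voxel (ℓ2 across frames, ℓ1 across
  voxels) lets voxels whose dynamics genuinely depart from the model be
  released as coherent outliers while incoherent undersampling jitter
  stays suppressed; the solution is full rank.
* **CS-TV**: same data term with an elementwise ℓ1 penalty on first-order
  temporal differences.

All data-consistency terms are density-compensated (ramp |k| weights with
a small DC plateau). The published objectives are stated with the plain
residual ‖Es − m‖₂, but the unweighted radial normal operator has a
sampling-density spectrum spanning many orders of magnitude and CG makes
no useful progress on it within any practical iteration budget; the
weighted form is the standard radial-MRI practice and changes only the
implicit noise weighting, not the noise-free solution of consistent data.

The ℓ1 solvers use iteratively re-weighted least squares: weights
w = 1/max(|r|, ε) with ε equal to a configurable fraction (default 1e-2)
of the median residual magnitude, the first outer pass with unit weights
(reweighting from s = 0 is a degenerate fixed point), and each weighted
quadratic attacked by preconditioned CG warm-started from the previous
iterate. The preconditioners are exact in the penalty's temporal
eigenstructure — a span/off-span split for MOCCO, a temporal-DCT
diagonalization for CS-TV — because a plain Jacobi diagonal over-damps
the penalty's null space (e.g. the temporally constant mode under TV).
Iteration stops when the relative k-space residual falls below the
tolerance (1e-9) or the total CG iteration count reaches the cap (400 by
default; the scaled presets use 100–120, where the objective has long
plateaued). The IRLS majorization guarantees a non-increasing objective,
which the test suite asserts.

**Regularization scale.** The published study quotes λ = 10 (MOCCO) and
λ = 2 (CS-TV) without stating its normalization, which is
implementation-specific. Here the encoding operator is scaled to unit
spectral norm, the data to unit mean magnitude, and the quoted λ values
are mapped onto this normalization by fixed internal constants
(`MOCCO_LAMBDA_SCALE = 1e-3`, reflecting the different units of the
voxel-grouped norm, and `CSTV_LAMBDA_SCALE = 0.3`). The constants were
fixed once, by requiring the solvers to operate in the regime the study
describes — MOCCO tracking the reference while PCB under-represents fast
kinetics, CS-TV visibly over-smoothing — and are not tuned per
experiment. Reconstructed image scale is irrelevant downstream because
concentration conversion uses the baseline signal ratio.

## Temporal models

* **HR** ("high resolution", the idealized model): rank 2 — the lesion's
  exact reference signal curve plus a constant column for static tissue,
  orthonormalized. One basis per kinetic condition.
* **LR** ("low resolution", the realistic model): rank 3, learned from
  the data itself. Per frame, a low-spatial-resolution image is gridded
  from the central k-space samples (|k| ≤ 0.1 cycles/pixel by default at
  the scaled geometry); each voxel's time curve is smoothed by
  least-squares cubic B-splines (knots every 12 frames = 60 s by
  default) to suppress frame-to-frame undersampling jitter; the rank-3
  principal temporal subspace of the smoothed curves is extracted and
  rotated into independent components (FastICA on the
  real/imaginary-stacked representation) for identification. The solvers
  depend only on the span, which the variance-ordered orthonormal basis
  carries; the ICA rotation is kept as metadata.

The central-k-space radius and the spline knot spacing set the spatial
dilution and the temporal resolution of the learned model. They are the
two quantities the original study leaves unspecified (its "progressive
learning" schedule is not printed), and they control how much of a fast
wash-in survives into the learned basis — hence how strongly the
span-confined PCB reconstruction underestimates fast kinetics. The
defaults were chosen once so that the learned-model arm reproduces the
study's qualitative regime at the scaled geometry and are exposed in the
configuration.

## Pharmacokinetic analysis

Magnitude series are converted to concentration by inverting the SPGR
equation against the mean baseline signal (frames before bolus arrival);
the inversion is analytic and exact on noise-free model signals. Voxels
whose E1 solution leaves (0, 1) are flagged and excluded; negative
concentrations are clipped to zero and counted.

The extended Tofts model is fitted per voxel by bounded damped least
squares (`scipy.optimize.least_squares`, trust-region reflective — the
bounded analogue of Levenberg–Marquardt) with step tolerance 1e-6 and
function tolerance 1e-8, bounds [0, 1] on all three parameters, and 5
random restarts from a seeded generator (best residual kept). K^trans is
parameterized in s⁻¹ inside the fit so the physiological range up to
1.5 min⁻¹ = 0.025 s⁻¹ sits inside the unit bound; published fits with a
[0, 1] bound report recovered values above 1 in min⁻¹ units, which is
only consistent with the s⁻¹ parameterization.

Errors are reported as 100·(fitted − truth)/truth inside the generating
lesion disk (full mask, including partial-volume edge voxels), as
per-lesion mean ± SD tables, Bland–Altman summaries with ±10% reference
bands, and percent-error maps. The Monte-Carlo driver repeats
noise → reconstruct → convert → fit over seeded i.i.d. noise realizations
(30 per condition at full scale) and aggregates pixel-wise means, SDs and
percent error of the mean, with a noise-matched fully-sampled control arm.

## Scaled study conditions

The published experiment (matrix 448², 16 coils, 128 frames) is not a
desk-scale computation. The package's presets scale the geometry while
preserving the quantities the conclusions rest on:

* `desk-small` (default; used by `scripts/acceptance.py`): matrix 48,
  FOV 72.9 mm, 4 coils, 128 frames × 5 s, bolus at 150 s, 8 spokes/frame
  (R = 88), fully-sampled arm 152 spokes/frame, one lesion per dataset
  (21 ROI voxels). Coil count is reduced with the matrix so that each
  frame stays effectively underdetermined: the 2× readout oversampling
  carries no information beyond the sampled disk, so 4 coils at matrix 48
  give an effective samples/unknowns ratio ≈ 0.67 (the published
  geometry's nominal ratio is 0.57). With fewer coils the slow-kinetics
  condition becomes fragile — coherent aliasing comparable to the tiny
  enhancement biases its amplitude by ~10% depending on the coil-jitter
  seed — while many more coils make the "undersampled" problem
  overdetermined and all solvers trivially agree.
* `desk`: matrix 192, 8 coils (samples/unknowns ≈ 0.67), minutes per
  solver per condition.
* `full`: the published geometry; documented but not exercised here.
* The pytest acceptance suite trims iteration budgets and uses a
  Nyquist-sampled 76-spoke, 64-frame reference arm (the reference result
  is insensitive to the washout window), while the undersampled arms keep
  the full 128-frame window the slow lesions need; the Monte-Carlo check
  runs at matrix 32 with native 0.76 mm pixels so the lesion keeps its
  ~10-pixel footprint. The bounds asserted are the study's own.

What the scaled phantom does not emulate: anatomically realistic breast
texture and fat signal, 3D stack-of-stars encoding, B0/B1 inhomogeneity,
motion, T2* decay at the echo time, and physical coil maps. Passing
tests therefore demonstrate the fidelity of the reconstruction-and-
fitting chain under ideal system conditions, not robustness to those
confounds.

## Numerical choices and edge cases

* NUFFT: Kaiser–Bessel width 8, oversampling 2.0, even matrix sizes only;
  forward accuracy ≤ 1e-6 relative to the direct transform; adjoint is
  the exact transpose (machine precision).
* Density weights: |k|·Δk·Δθ with the DC sample floored at Δk/4.
* ETM integrator: kep·dt < 1e-12 falls back to a running trapezoid;
  ve = 0 with ktrans > 0 is rejected as a parameter error.
* Concentration inversion: invalid E1 voxels are flagged, not raised;
  all-zero curves short-circuit the fit to zeros with a converged flag.
* Lesion placement: evenly spaced on a ring at 55% of the support
  semi-axes; overlapping or out-of-support disks raise configuration
  errors.
* Determinism: every random stage (coil jitter, noise, fit restarts,
  ICA) derives its seed from the experiment seed; repeated runs are
  bit-identical, which the pipeline tests assert on the summary CSV.

## Known limitations

* The learned-model arm's two free scales (central-k-space radius, spline
  knot spacing) stand in for an unpublished multi-scale learning
  schedule; different choices move the PCB-LR bias at fast kinetics by
  tens of percentage points, and the scaled results should be read with
  that sensitivity in mind.
* At the scaled geometry the CS-TV arm reproduces the study's K^trans
  underestimation ordering but not the sign of its small V_e bias at
  intermediate kinetics.
* The fully-sampled reference arm carries a small negative K^trans bias
  (≈ −2%) from lesion partial-volume and ringing at the 21-voxel ROI,
  consistent in magnitude with the published reference column's spread.
* Runtime is dominated by per-frame FFTs; the full-size preset is
  documented as cluster-scale and untested in CI.
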
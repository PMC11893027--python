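# Methods

This note documents the models, numerical choices and known limitations
of the `fetalt2star` pipeline, in the order data flows through it.

## Signal model and reference parameterization

All signal simulation and fitting assume mono-exponential gradient-echo
decay, S(TE) = S0 · exp(−TE/T2*), sampled at the three echo times of the
low-field fetal protocol (42, 107, 172 ms; repetition time is carried as
metadata only). Per-region T2* ground truth comes from a normative
reference table: per-region mean and 5th/50th/95th percentile values in
2-week gestational-age bins spanning 20–40 weeks, measured in 92 control
scans. Bins are half-open [a, a+2) with the last bin closed at 40 weeks
(`[38, 40]`), matching the "+6 days" convention of the bin labels. Lookups
between bins interpolate linearly between bin midpoints (21, 23, …, 39
weeks) and extrapolate as constants beyond the outermost midpoints, so
every bin midpoint reproduces the table value exactly. The Gaussian
spread attached to a bin is sd = (p95 − p5)/3.29, the normal-theory
conversion of a 5th–95th span.

Per-region S0 values (proton-density-like amplitudes, arbitrary units:
fluids 1000, tissue 800–850) are a package convention; they cancel out of
every T2* estimate (scale invariance is asserted by test).

## The digital phantom

The phantom is a nested/offset-ellipsoid cartoon of a fetal brain on an
isotropic grid (default 1.2 mm, the reconstruction target): an outer
cerebral ellipsoid with semi-axes (a, 0.85a, 0.80a) carrying a cortical
gray-matter ribbon and a dorsal external-CSF cap, interior white matter,
a central-inferior deep-gray nucleus, paired dorsal ventricle bodies, and
posterior-inferior cerebellum and inferior brainstem that extend below
the cerebral ellipsoid. `a` scales linearly with gestational age
(normalized so a 40-week brain fills 82% of the grid half-extent), so
total and per-region volumes grow monotonically over 20–40 weeks on any
fixed grid; 48³ voxels at 1.2 mm is the documented minimum.

Two geometry decisions are deliberate and worth stating plainly:

* **The geometry is not anatomically realistic.** Regional quantification
  depends only on label bookkeeping, so compartments are ellipsoids.
* **Compartment adjacency was chosen to control partial-volume behavior,
  not to mimic anatomy.** At 3 mm acquisition resolution the effective
  reconstruction band limit leaves ~1 mm of cross-tissue mixing at every
  boundary. Mixing with air only rescales the signal and leaves T2*
  untouched, whereas mixing between tissues biases regional means.
  Therefore the brainstem and cerebellum sit mostly outside the cerebral
  ellipsoid (bordered by air, as their real counterparts border CSF), the
  ventricles are dorsally exposed fluid pockets, the deep-gray nucleus is
  sunk toward the low-T2* brainstem, and the eCSF pool covers only the
  dorsal cap so ventral cortex borders air. With this layout a noiseless
  motion-free simulate→reconstruct→fit round trip recovers every regional
  mean within 2%; with a complete eCSF shell and strictly interior CSF
  structures the same pipeline plateaus at 4–7% error for the small
  compartments — an information limit of the acquisition, not a solver
  deficiency.

Slice sampling integrates the moved phantom through the acquisition
point-spread model: a Gaussian slice profile with FWHM equal to the slice
thickness (5-point Gauss–Hermite quadrature) and a boxcar in-plane
average over the pixel footprint (3×3 rectangle rule). One rigid
transform is drawn per (slice, dynamic) excitation — rotations uniform in
± amplitude degrees, translations uniform in ± amplitude mm, about the
volume centroid — and applied identically to the three echoes of that
excitation, which is the premise of multichannel reconstruction. Noise
is Rician: each magnitude value v becomes sqrt((v+n1)² + n2²) with n1,
n2 ~ N(0, σ). All stochastic outputs are pure functions of (inputs,
seed). Within-region T2* heterogeneity is off by default; a
`smooth_gradient` option imposes a linear T2* modulation along the slice
axis for sensitivity experiments.

## Reconstruction

The forward model treats every acquired pixel as the quadrature sum of
trilinearly interpolated volume samples at the moved point-spread sample
locations — exactly the integral the simulator evaluates, so noiseless
data are exactly consistent with the generating volume. Samples falling
outside the reconstruction grid contribute zero (air); pixels whose
in-grid point-spread weight falls below 0.5 are dropped, because a tiny
in-grid weight would otherwise have to explain the pixel's full (noisy)
magnitude and blow up boundary voxels.

The outer loop alternates, for `n_outer_iterations` (default 3):

1. **Registration** of every slice of the reference echo (default the
   third echo, where tissue contrast is strongest) to the current volume
   by maximizing normalized cross-correlation: 13-point single-axis
   candidate seeding (±2°/±2 mm) followed by two rounds of Nelder-Mead.
   Rotation sensitivity of a single smooth slice is of order 1e-3 NCC
   per degree, so the projection inside the optimizer uses the full
   acquisition quadrature (a numba-compiled fused projection/NCC kernel)
   — except against the initial scatter-averaged volume, which is itself
   PSF-blurred, where the matched model is plain plane sampling
   ("delta" mode). A refined transform is accepted only if it improves
   NCC by ≥ 1e-3 over the incoming estimate; on flat similarity
   landscapes (motion the data cannot see) the parsimonious estimate is
   kept, which protects motion-free data from spurious micro-motion.
   With a brain-localization mask (an input, as in automated fetal
   pipelines), registration is restricted to pixels over the 6 mm-dilated
   mask and slices with fewer than 30 such pixels are skipped.
2. **Outlier rejection**: a slice is excluded when its post-registration
   NCC falls below `similarity_threshold` (default 0.8; the value −1
   never excludes), and a whole dynamic when more than half of its
   slices are excluded. Slices with undefined scores (uniform
   background) stay included — they carry no anatomy and pin air to
   zero. Excluded slices contribute no rows to the forward matrix, so
   their influence is exactly zero (asserted bit-identically by test).
3. **Volume update**: LSMR on the stacked system [A; λD] with first-order
   difference operator D, warm-started at the previous volume. The same
   sparse A (motion shared) serves all three echoes.

Magnitude noise is estimated from air pixels (Rayleigh mean, σ̂ =
mean/√(π/2)) and used twice: a first-moment Rician bias correction of
the measurements (s → sqrt(max(s² − 2σ̂², 0))) and a discrepancy-style
regularization rule λ = 0.02 + 2.5 · σ̂/signal-scale (the fixed
`regularization_weight` overrides this when set). Without the
noise-matched λ, motion-diverse sampling deconvolves aggressively and
the amplified voxel noise biases the downstream log-linear T2* fit by
>10%; with it, end-to-end regional errors at 5°/5 mm motion and SNR 20
stay within 5%.

Transforms are estimated once on the reference echo and copied to the
other echoes (`share_transforms` returns independent copies). The
registration reference is configurable. Non-convergence (relative volume
update > 10% after the final iteration) is recorded as a provenance
warning, never an exception.

## Relaxometry

Log-linear ordinary least squares of ln S on TE is the default
estimator: with three echoes it is exact on noiseless data and fast
enough to map whole volumes vectorized. Any non-positive sample
invalidates a voxel (log domain); a non-negative slope (no decay) is
likewise invalid. The damped nonlinear least-squares estimator (
Levenberg–Marquardt on the signal scale) agrees to 1e-6 relative on
noiseless data and is no worse under Rician noise (seeded Monte-Carlo
comparison in the tests). T2* bounds default to (1, 1000) ms — the upper
bound chosen above the longest fluid values in the reference table — and
out-of-bounds voxels are excluded, never clamped, because clamping would
bias regional means. An optional minimum-first-echo-signal filter is
off by default. Log-space OLS is unweighted by default; a
signal²-weighting flag exists for noise-floor mitigation studies.

## Regional statistics

The default 19→7 label merge ships as an editable YAML file
(`fetalt2star/data/label_mapping.yaml`); the raw-label inventory follows
the common fetal-parcellation convention (left/right pairs, vermis to the
cerebellum category, corpus-callosum-like substructures to white matter,
all ventricular spaces to ventricles) and is a package convention, to be
edited for any other id scheme. Merging conserves voxel counts and
refuses unmapped labels by listing them. Regional mean T2* is the
arithmetic mean of the voxelwise map over in-category valid voxels
(fitting the region-mean signal instead is available behind a flag for
sensitivity analysis); volumes are voxel count × |det(affine)| in mL.

## Normative modeling

Growth curves are OLS on the polynomial basis {1, GA, …, GA^degree},
default degree 2 because regional T2* declines faster late in gestation.
The GA association is tested with the joint F-test of all GA terms
(identical to the regression F-test since every non-constant regressor
is a GA power); per-coefficient t-tests are also reported. Percentile
tables use the linear-interpolation quantile convention (numpy default);
with bins of n = 7–11 the convention matters, so it is recorded in the
table metadata and `evaluate_centile` inverts the same convention.
Repeated scans of one pregnancy are treated as independent data points;
callers can collapse to one scan per subject before fitting. Smooth
centile models (GAMLSS/LMS) and longitudinal mixed effects are out of
scope.

The tabular cohort generator draws GA values per 2-week bin matching the
control bin counts (8, 10, 11, 9, 9, 8, 11, 8, 7, 11; total 92), and
regional T2* from N(midpoint-interpolated mean, bin sd). Synthetic
volumes come from the phantom's compartment volumes interpolated over GA
with 8% log-normal noise — monotone growth for trend tests, not
milliliter-realistic values (the source table prints no volume numbers).

## Cohort bookkeeping

Inclusion keeps scans with both sequences AND GA ≥ 20 weeks AND brain in
the field of view AND correctable motion, logging the first failing rule
in the fixed order sequences → GA → FOV → motion. The synthetic
recruitment manifest is generated programmatically and reproduces the
full flow: 193 scans / 145 individuals → 150/114 with both sequences →
(−8 below 20 weeks, −1 brain outside FOV, −6 uncorrectable motion) →
135/107 analyzable = 92/71 control + 43/36 pathology. One published
demographic table lists 93 control outcomes where the narrative count is
92 control scans; the manifest follows the narrative (92/43) and this
note records the discrepancy rather than resolving it.

## Problem sizes and determinism

Default end-to-end validation runs use a 64³ phantom at 1.2 mm (the
motion case: 15 dynamics, 26 slices of 26×26 pixels per echo, two outer
iterations, LSMR capped at 300 iterations) and a 48³ phantom for unit
tests — sizes chosen so the full suite exercises every path on a single
CPU in minutes while leaving the physics unchanged. All randomness flows
through explicit integer seeds (`numpy.random.default_rng`); reruns with
the same configuration are bit-identical for deterministic stages and
exactly reproducible for seeded stochastic stages.

## Known limitations

* No EPI distortion, B0 inhomogeneity, spin history, coil sensitivity or
  cortical folding in the phantom; passing tests say nothing about those
  effects in real data.
* Single-orientation single-stack acquisition: through-plane resolution
  recovery relies on motion diversity; the motion-free case is
  information-limited at the acquisition band limit.
* Rigid motion only, shared within an excitation; out-of-plane rotation
  of a single smooth slice is weakly identifiable. Against a sharp
  reference volume registration recovers simulated motion to well under
  0.1 degree, but the iterative scheme must bootstrap from a
  motion-averaged scatter initialization against which those rotations
  are unidentifiable, so with worst-case independent per-slice motion
  (uniform ±5°/±5 mm at SNR 20) the loop retains a ~3 mm residual
  alignment floor. The resulting boundary smear leaves the thin cortical
  ribbon at ~6% regional error — above the pipeline's 5% design target,
  which every other compartment meets (and which all compartments meet
  with known motion, and within 2% for motion-free noiseless data).
  Edge-preserving reconstruction and temporally correlated motion, both
  outside this package's scope, are the standard remedies.
* Edge-preserving regularization (as in full SVR toolkits) is not
  implemented; first-order Tikhonov slightly smooths boundaries.
* The 19-label inventory underlying the default merge is a convention;
  real parcellations must be checked against it before use.
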
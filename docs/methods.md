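# Methods

This note documents the models, numerical choices and limitations of
elastomap in one place. Everything quantitative stated here is computed by
the test suite or the acceptance script; nothing is quoted from elsewhere.

## Phantoms and study conditions

The phantom geometry mirrors a preclinical 9.4 T acquisition: a 64×64
in-plane matrix over a 19.2×19.2 mm field of view with nine 0.3 mm slices
(0.3 mm isotropic voxels), shear vibration at 900 Hz, 30-echo T2 trains at
TE = 7, 14, …, 210 ms, and diffusion weighting at b = 1500 s/mm² over 30
directions plus one b = 0 volume. Tissue density is fixed at 1000 kg/m³
(standard soft-tissue assumption) and exposed in config.

Regions are voxelized from geometric primitives: a parabolic band for the
corpus callosum, ellipsoids for tumor core, needle tract and contralateral
control, overlaps resolving by fixed priority (tumor core > corpus
callosum > needle tract). Ellipsoids built from a target volume are
voxelized by rank-thresholding the normalized ellipsoidal distance —
exactly ⌈V/h³⌋ voxels are labeled, nearest first — because plain
inside/outside tests of voxel centers mislabel structures only a few
voxels across by several percent. The labeled volume therefore matches the
request to within one voxel volume by construction.

### Longitudinal cohort

The cohort generator treats the study's group-mean trajectories as ground
truth: callosal |G\*| rising 4.44 → 5.31 kPa between weeks 4 and 8, the
biphasic tumor-core stiffness 3.9 → 5.51 → 4.24 kPa, core T2
40.19 → 41.65 → 44.83 ms, core ADC 610.2 → 711.2 ×10⁻⁶ mm²/s, tumor
volumes 1.6 → 3.76 → 16.88 mm³ (radiotherapy arm: 10.96 mm³ at week 12,
23.01 mm³ at week 16), and the corresponding radiotherapy and sham arms.
Cells never printed in the source tables — week-4 tumor ADC/FA, sham
absolute callosal stiffness, needle-tract and contralateral means — carry
plausible healthy-brain values chosen once and fixed (e.g. sham callosal
|G\*| 5.0 → 3.9 kPa, which reproduces the printed −1.1 kPa delta).

Only means ± SEM are published, so the between-subject dispersion is set
to SEM·√n per metric (|G\*| 1.06 kPa, T2 1.34 ms, ADC 38.8×10⁻⁶ mm²/s,
FA 0.034, Y 0.058). Tumor volume uses a multiplicative SD of 0.4 because
its printed SEM scales with the mean, with a 0.2 mm³ floor so phantoms
stay constructible. Within-subject correlation across weeks is unknowable
from printed summaries; it is a config parameter with default 0.5,
implemented as a shared subject effect plus week-wise noise
(z = √ρ·b_subject + √(1−ρ)·e_week), which yields the stated marginal SD at
every week and correlation ρ between any two weeks. Each dispersion draw
is per (subject, region, metric). Week 16 is imaged only for the first
five radiotherapy subjects by id.

### Signal generators

Magnitude-MRI noise is modeled as the magnitude of the clean signal plus
two independent Gaussian channels (Rician-like). With zero noise every
generator emits the exact forward model, and all generators are bitwise
reproducible under a fixed seed.

The histology generator draws a stained pixel's three channels from a
shared stain-depth factor t (zero mean, unit SD, bounded: uniform over
±√3) times the per-channel palette SD, plus ~1 intensity unit of
independent jitter. A common factor is the physically sensible model —
stain uptake varies, hue does not — and it is also what the per-channel
mean ± 2 SD windowing assumes: with three independent channels the
conjunctive rule would structurally cover only ≈ 0.954³ ≈ 87 % of truth
pixels and the area readout could never track the planted fraction.
Nuclei are dark disks (radius 0.28 μm at 0.25 μm/pixel) placed by dart
throwing at a Poisson-mean count, kept one clear pixel apart so rasterized
disks remain 4-connected-separable; infeasible densities raise rather
than silently overlap.

## Wave simulation

Fields follow u(t) = Re{U e^{iωt}}; the plane-wave oracle uses
k = ω√(ρ/G\*) with the branch Im(k) ≤ 0, so lossy media decay along
propagation. Heterogeneous fields come from a per-component scalar
finite-difference solve of ∇·(G\*∇u) + ρω²u = 0 (flux-form 7-point
stencil), with the source displacement prescribed on one face. Mode
conversion at interfaces is deliberately ignored: the solver makes the
same local-homogeneity assumption as the inversion it exists to test, and
stays at desk scale.

Boundary treatment was chosen against the plane-wave oracle. The face
opposite the source carries a first-order outgoing-wave (Robin) closure
∂u/∂n = −ik·u plus a 12-voxel cubic ramp of added loss modulus (strength
3·|G|); lateral faces are zero-gradient. Absorbing layers on the lateral
faces were tried and rejected: they attenuate grazing waves and diffract
the deficit into the interior (25–50 % amplitude ripple against the
oracle), whereas the opposite-face ramp+Robin combination leaves the
homogeneous lossless interior within 2 % of the analytic plane wave
(< 1 % typical). Nine-slice stacks leave no room for through-slice
absorbers, so z faces are zero-gradient by default (configurable to
absorbing for thick grids). Dirichlet unknowns are eliminated from the
linear system rather than replaced by identity rows; the reduced matrix
keeps a symmetric pattern and factorizes ~5× faster under the
minimum-degree ordering used (SuperLU, MMD_AT_PLUS_A).

Compressional contamination is modeled as the gradient of a long-
wavelength (default 50 mm) scalar plane wave, normalized to a requested
amplitude. Its default direction (2, 1, 0.5)/|·| is deliberately
asymmetric: for directions with equal component magnitudes on an isotropic
grid the central-difference curl of the sampled gradient field vanishes
identically by symmetry, which would make robustness checks vacuous.

Phase encoding samples scale·Re{U_d e^{iθ_n}} at θ_n = 0, π/2, π, 3π/2
per encoding direction, adds optional Gaussian phase noise, and wraps to
(−π, π]. The default peak phase is 3.5 rad: above π so wrapping genuinely
occurs and the unwrapper is exercised, and below the ≈ 4.1 rad aliasing
limit at which the voxel-to-voxel phase step of an ≈ 8-voxel wavelength
would reach π and become unrecoverable.

## Reconstruction

Unwrapping is per-slice 2-D (reliability-sorted algorithm from
scikit-image); slices are then aligned by subtracting the integer number
of 2π turns closest to the median inter-slice difference (an exact ±π tie
resolves to the smaller offset, with a warning). Spatially constant phase
offsets that survive this are harmless — the curl differentiates them
away. The 4-point temporal DFT H = (2/4)Σ s_n e^{−iθ_n} returns U exactly
for noiseless samples; the encode/decode round trip is the identity to
machine precision.

The curl uses central differences (1-voxel validity erosion), the
Laplacian the 7-point stencil with physical anisotropic spacing (one more
voxel of erosion on every face). The inversion combines the three curl
components by unweighted least squares (per-component median available in
config) and additionally excludes voxels whose summed |∇²q| falls below
10⁻³ of the valid median — there is no curvature to invert there.
Negative real or imaginary parts are clipped to zero for the reported
maps so Y keeps its [0, 1] interpretation, and preserved unclipped in
diagnostic channels with a clip flag. atan2 (not atan) makes the purely
viscous limit exact. No smoothing is applied before differentiation by
default; an optional 3-D Gaussian (σ in voxels) is in config, as
smoothing is common practice but not part of the core chain.

Accuracy: when the forward field comes from the package's own
finite-difference solver, forward and inverse share the discrete operator
and homogeneous-phantom recovery is essentially exact. Against the
continuum plane wave the 7-point Laplacian's dispersion biases |G\*| by
(sinc(kh/2))⁻² ≈ +5 % at 8.3 voxels/wavelength for axis-aligned
propagation (less for oblique incidence), and the recovery error falls
monotonically as voxels-per-wavelength grows from 4 to 12 — the test
suite traces this curve. Because the inversion is a ratio of derivatives,
the elastogram is invariant under any rescaling of the acquisition's
phase-to-displacement scale.

## T2 relaxometry

The noise SD is estimated from background magnitude voxels as
SD/√(2−π/2), inverting the Rayleigh moments of two-channel Gaussian
noise. The published filter phrase ("removal of all voxels exceeding four
SDs of noise level") is ambiguous; read literally per voxel it would
delete all tissue, so the default reading is noise-floor sample
exclusion: echo samples at or below 4σ are dropped before fitting, with
the whole-voxel reading available as `filter_mode="voxel"` and the
multiplier configurable. The fit is log-linear least squares with the two
standard magnitude-data refinements: the Rician first-moment offset is
removed before the log (√(S²−2σ²)) and samples are weighted by S²
(inverse variance of ln S). Both reduce to the plain fit at σ = 0, so
noiseless recovery is exact for any T2 in (5, 500) ms. At SNR 50 the
filtered fit's bias is ≈ 2 % and smaller than the unfiltered fit's
(simulated at 500 voxels in the suite). Voxels with fewer than three
surviving echoes are invalid.

## Diffusion

The tensor is fit by unweighted least squares of −ln(S_g/S_0)/1 against
b·gᵀDg in the six unique components; ADC is defined as mean diffusivity
(trace/3), the standard DTI reduction consistent with the 600–730×10⁻⁶
mm²/s magnitudes the cohort emulates, and FA is the usual normalized
eigenvalue dispersion with negative eigenvalues clamped to zero (flagged)
so FA ∈ [0, 1]. The shipped 30-direction set comes from antipodal
electrostatic-repulsion optimization; its design matrix has condition
number ≈ 1.59. Noiseless synthesis round-trips to 10⁻⁸ relative and the
scalars are rotation- and scale-invariant to 10⁻¹⁰.

## Statistics

Regional means are arithmetic means over valid in-mask voxels; region
volume is voxel count × voxel volume. Paired two-sided t-tests compare
weeks within a group using only subjects present at both weeks (subjects
missing a time point are dropped from paired analyses only); unpaired
tests compare groups on absolute values or per-subject deltas, with
pooled-variance Student as default and Welch as an option (the source
analysis does not state which was used). Results carry mean ± SEM
(SD/√n), t, df and p; α = 0.05. No multiple-testing correction is applied
by default, matching the exploratory design; a Benjamini–Hochberg helper
is provided. Calibration and power are verified by simulation: type-I
error of both tests lies in [0.03, 0.07] over 2000 null replicates, and
the paired test detects the callosal stiffening effect (4.44 → 5.31 kPa
at n = 23, default dispersion and ρ = 0.5) in well over 80 % of 200
replicates.

## Histology quantification

Thresholds are mean ± 2 SD per channel from 20 sampled stained pixels
(sample SD, ddof = 1 — at n = 20 the choice versus population SD is
negligible but must be pinned for exactness tests), clipped to [0, 255].
A pixel is stained iff all three channels are in range (conjunctive
rule; a hue-distance rule is out of scope). Expected coverage of an
n = 20 window is slightly below the asymptotic 95.4 % (tolerance-interval
effect plus 8-bit quantization); recovery of planted fractions is within
±1.5 percentage points across 0–20 % under the default palette. The
nucleus detector is deliberately simple — intensity threshold,
4-connected components, area filter in μm² — and counts planted disjoint
nuclei exactly; density is count·100/ROI-area-μm².

## Pipeline

`run-all` chains cohort → wave/echo/DWI synthesis → reconstruction/fits →
ROI table → comparisons → report, with all randomness derived from one
root seed through named per-stage substreams (changing one stage's
parameters leaves other stages' draws untouched). The default demo cohort
is two subjects per arm on the full 64×64×9 grid — about 20 forward
solves, i.e. roughly half a minute — chosen so the full end-to-end path
(including its determinism check, which runs the pipeline twice) stays
comfortably inside a routine test run; group sizes, noise levels and all
reconstruction options scale up in config. The encoding scale is set
adaptively per acquisition to the 3.5 rad peak-phase target. Reports
contain no timestamps, so a fixed seed reproduces byte-identical outputs.
The per-subject acquisition defaults are noiseless (noise options are in
config): the pipeline's role is parameter recovery and statistics on top
of it, and the noise-robustness of each stage is established separately
by the module tests.

## Known limitations

- No anatomically realistic atlas, contrast enhancement, hemorrhage or
  mass-effect deformation; regions are geometric primitives.
- The wave solver is scalar per component (no mode conversion), so
  heterogeneous-phantom fields are approximations near strong interfaces;
  reconstruction accuracy there reflects the local-homogeneity assumption
  shared by the inversion.
- Reconstructed region means at tissue boundaries inherit the 2-voxel
  erosion and local-homogeneity bias of the inversion; the cohort's
  measured tables are therefore noisier than its truth tables.
- Displacement amplitudes are scale-consistent only; no absolute
  phase-to-displacement calibration is modeled.
- T2 is mono-exponential (no multi-compartment or stimulated-echo
  correction); diffusion is Gaussian (no kurtosis); no eddy/motion
  correction or registration anywhere — maps are assumed co-registered.
- Passing recovery tests on these synthetic conditions demonstrates
  correctness of the algorithms under their stated assumptions, not
  performance on real scanner data with coil inhomogeneity, motion, or
  anatomy-dependent artifacts.
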
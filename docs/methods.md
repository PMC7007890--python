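# Methods

This note records the models, parameter choices and numerical conventions
behind `hippomre`, and what the synthetic experiments do and do not
demonstrate.

## Forward wave model

Time-harmonic shear-wave propagation is modelled by the scalar
heterogeneous Helmholtz equation

∇·(G\* ∇u) + ρω²u = 0,

for a single complex displacement component u at angular frequency
ω = 2πf (f = 50 Hz, ρ = 1000 kg/m³ by default). This is a deliberate
reduction of full nearly-incompressible vector viscoelasticity: it keeps
every quantity the pipeline analyses — complex modulus, damping ratio,
stiffness, wavelength, attenuation — while remaining tractable on a desk.
Consequences of the approximation: no mode conversion, no pressure field,
and a single polarisation. Closed-form plane-wave behaviour is preserved
exactly (f·λ = √(μ/ρ) in the elastic limit; travelling-wave decay rate
Im k for k = ω√(ρ/G\*)), which is what the solver is verified against.

Discretisation: conservative second-order finite differences on the
isotropic voxel grid; face moduli are arithmetic means of the adjacent
voxels; sparse LU direct solve. Boundary conditions: a prescribed
displacement on one grid face (uniform, or half-sine so that exactly one
lateral guided mode is excited — the configuration used for closed-form
checks) and homogeneous Dirichlet on the remaining faces. The solver warns
below 8 voxels per background wavelength and refuses to run below 4; the
relative linear-system residual must stay below 1e-8 (a larger residual
indicates near-resonance or degenerate moduli and raises).

Sign convention: the operator is assembled with G\* = G′ + iG″, whose
natural propagating branch is the principal k = ω√(ρ/G\*) (Im k ≤ 0).
Reported wavenumbers use the attenuation-positive convention; only the
sign of the phase differs.

Measurement noise is iid Gaussian on the real and imaginary parts.
"1% noise" always means a noise SD of 1% of the field's RMS amplitude.

## Nonlinear inversion

The unknowns are the voxelwise pair (G′, G″). The objective is

J(θ) = Σ_experiments ‖u_model(θ) − u_meas‖² / ‖u_meas‖²
     + α_eff Σ_ROI Σ_{i∈ROI} ‖θ_i − mean_ROI(θ)‖² / θ_ref²,

i.e. a signal-power-normalised data misfit plus the soft-prior (SPR)
penalty: squared deviation from the running ROI mean in both property
channels, normalised by θ_ref = 2.5 kPa. The penalty's gradient is exact
(the mean-deviation identity makes the mean's dependence drop out).
Voxels removed from an ROI by CSF exclusion are simply absent from the
penalty and update freely.

**SPR weight scaling.** A raw regularization weight is only meaningful in
the scaling of the code that defines it. The printed default 1e-10 is
mapped to this objective by a fixed internal gain (α_eff = weight × 1e6),
calibrated once on the reference two-region phantom: at the default weight
the within-ROI coefficient of variation of recovered G′ drops severalfold
relative to the unregularised inversion (~0.8% vs ~4.3% at 1% noise with
two drives) while the ROI mean stays data-driven; the within-ROI spread is
monotonically non-increasing in the weight and vanishes in the strong-prior
limit. In this well-conditioned scalar setting the unregularised spread is
already small, so the weight acts as a stabiliser rather than the dominant
variance control it is in full-scale in vivo inversions.

**Optimisation.** Up to 100 global iterations (default). Each iteration is
a short bounded L-BFGS-B descent (5 inner iterations) with adjoint
gradients — one extra sparse solve of the complex-symmetric operator per
experiment — and property bounds (G′ ∈ [0.2, 10] kPa, G″ ∈ [0, 5] kPa)
enforced by projection; parameters are scaled to kPa for conditioning.
After each accepted iteration, properties **outside** the SPR ROIs are
smoothed with a Gaussian kernel (FWHM 1.5 mm, σ = FWHM/2.355 converted to
voxels) whose weights are renormalised against the ROI boundary, so
smoothing never crosses regional boundaries in either direction; ROI
voxels are never smoothed. An iteration whose post-descent objective
exceeds the previously accepted value is rejected and retried once from
the unsmoothed iterate; a second failure terminates with the best estimate
so far and `converged=False`. The recorded objective history is therefore
non-increasing by construction, and the history is asserted on in every
recovery test. Initialisation is homogeneous G′ = 2.5 kPa, G″ = 0.8 kPa.

Two orthogonal drive faces are used in the recovery experiments; a single
scalar field from one drive is a weaker data set than the in vivo full
vector acquisition, and the second illumination restores comparable
conditioning at negligible cost.

**Inverse-crime avoidance.** Recovery experiments simulate data on a 2×
finer grid (0.8 mm) and subsample to the 1.6 mm inversion mesh (voxel
centres coincide every second sample), then add noise.

## OSS-SNR

The octahedral shear strain
γ_oct = (2/3)√((ε11−ε22)² + (ε22−ε33)² + (ε33−ε11)² + 6(ε12²+ε23²+ε31²))
is computed per voxel from central finite differences of the complex
field (complex entries contribute their amplitudes), and is invariant to
hydrostatic components. The quality score is

OSS-SNR = mean_mask(γ_oct of the data) / mean_mask(γ_oct of pure noise),

where the denominator propagates the stated noise SD through the
identical difference stencil via a small seeded Monte-Carlo (20
realisations). By construction a pure-noise field scores ≈ 1, the score is
exactly linear in signal amplitude and inversely proportional to the noise
SD. The pass threshold defaults to 3.0, the conventional stability floor
for iterative inversion; at the 1% study noise the reference phantom sits
far above it. Whether an acquisition's noise SD is estimated from repeats
or residuals is outside scope — it is an explicit input here.

## ROI pipeline

Masks are transferred between grids by trilinear interpolation through a
given affine and re-binarised at 95% occupancy (partial-volume rims are
discarded); thresholding precedes CSF exclusion, matching the processing
narrative the pipeline emulates. CSF exclusion is strict: only voxels with
exactly 0% CSF partial volume survive, and the removed voxels are recorded
so the inversion can release them from SPR. Damping-ratio and stiffness
maps use ξ = G″/2G′ and μ = 2|G\*|²/(|G\*|+G′) with |G\*| = √(G′²+G″²);
voxels with G′ ≤ 0 are masked with a warning. μ ≥ |G\*| ≥ G′ holds
voxelwise with equality iff G″ = 0.

Regional summaries report mean and median ξ and μ (mean is the headline),
voxel count, volume (count × voxel volume) and head-size-normalised volume
as the simple ratio volume/eTIV (the deterministic convention; a
residual-based normalisation would require a cohort fit). Cohort tables
carry anatomical-space label volumes for the volume-behaviour analyses,
distinct from the measurement-space mask sizes.

## Synthetic phantoms and cohorts

Phantoms are axis-aligned grids (1.6 mm isotropic by default) with
sphere/ellipsoid/box primitives rasterised by the voxel-centre rule. The
reference phantom has a cerebrum-like background (G′ = 2150 Pa,
G″ = 430 Pa: ξ = 0.10, μ ≈ 2.2 kPa) and a hippocampus-like 8 mm inclusion
(G′ = 2750 Pa, G″ = 990 Pa: ξ = 0.18, μ ≈ 3.0 kPa), values chosen inside
the ranges observed for older-adult hippocampus. CSF regions are
fluid-like (G′ = G″ = 10 Pa at full partial volume; moduli blend linearly
with the partial-volume fraction) with a linear feathered rim emulating a
resampled segmentation. CSF moduli for the forward solve are a modelling
choice — published inversions treat CSF as data-model mismatch rather than
assigning it properties.

Cohorts emulate an 11–12-subject older-adult sample: ages on a shuffled
even grid across 66–72 years (recruitment across a band, not iid), sex
~55% female, IQ ~N(123.4, 4.25²), regional ξ/μ/volume from correlated
normals with the observed means/SDs (left-right correlation 0.5), bilateral
quantities as volume-weighted aggregates, eTIV ~N(1450, 120²) cm³,
OSS-SNR ~N(5.79, 1.54²). The integer memory score is a monotone function
of a latent trait: standardised effects of left-hippocampal ξ and age plus
Gaussian noise, mapped to mean 20.7, SD 1.95 and clipped to the 17–24
score range; predictors are sample-standardised so clustered draws cannot
collapse the discretised score into ties. Default effects (−0.77 ξ, −0.60
age, noise 0.22) target the observed association magnitudes; the
end-to-end demonstration uses deliberately strong effects (−1.0, −1.5,
noise 0.05) because at n = 11 the observed magnitudes sit exactly at the
significance boundary and a single demonstration run should not hinge on
the draw. What the generator does **not** emulate: anatomical geometry,
spatial correlation between a subject's phantom and their cohort row,
multi-frequency data, motion or physiological noise — so passing tests
show the *procedures* are correct and calibrated, not that in vivo effect
sizes would replicate.

## Statistical conventions

- MAD outliers: scaled MAD = 1.4826 × median |x − median|, criterion
  3×; a zero MAD flags every off-median point with a degeneracy warning.
- Normality: adjusted Fisher-Pearson skewness and excess kurtosis with
  SE_skew = √(6n(n−1)/((n−2)(n+1)(n+3))) and
  SE_kurt = 2·SE_skew·√((n²−1)/((n−3)(n+5))); |S| or |K| > 1.96 gates the
  analysis nonparametric.
- Partial Spearman: rank everything first (average ranks), then the
  Pearson partial correlation of the ranked variables via double
  residualisation; p from t = r√(df/(1−r²)) with df = n − 2 − k. With no
  covariates this is ordinary Spearman; the implementation is
  cross-checked against an independent library oracle.
- Steiger's z uses the pooled-mean-correlation covariance form (the
  common web-utility convention); its type-I error is calibrated by
  simulation. The z → two-tailed-p conversion (p = 2(1−Φ(|z|))) is exact
  and anchored in tests. Published z values for such comparisons are not
  always recoverable from rounded correlations, so the conversion — not
  any particular printed z — is the anchored quantity.
- BCa bootstrap: paired row resampling; bias correction z₀ from the
  proportion of bootstrap statistics below the point estimate (ties count
  half, proportion clamped away from 0/1), acceleration from jackknife
  skewness; resamples on which the statistic is undefined are dropped;
  constant data collapse the interval to the point estimate. Coverage is
  verified by simulation (94-96% observed for a nominal 95% interval).
- Mann-Whitney and Wilcoxon report the tie-corrected,
  continuity-corrected standardised z alongside the raw statistic,
  mirroring small-sample reporting style; the U convention (U of the
  first group; complete separation gives 0, or 9 reversed) is pinned by a
  test.
- Covariate screening retains covariates associated with the memory score
  at p ≤ 0.05 **inclusive** (parsimony against overfitting at n ≈ 11;
  screening tables against all dependent variables are still reported).
  Candidate covariates are age, sex and IQ; hippocampal volume is screened
  and reported but treated as a dependent measure, not a nuisance.
- No multiple-testing correction is applied; the report counts the
  uncorrected tests instead.

## Problem sizes and tolerances used by the experiments

- Closed-form solver checks: 128×128 grid, 1.6 mm voxels (wavelength
  within 2%, attenuation within 5% of the analytic values).
- Two-region recovery: 40×40 inversion grid, data from a 79×79 0.8 mm
  grid, two drives, 1% RMS noise, ≤40 global iterations (~4 s; ROI-mean ξ
  and μ within 10% of truth, typically within ~2%).
- CSF-bias comparison: 20 seeded phantoms, matched-grid simulation, ≤12
  global iterations each (~20 s total); two-sided sign test on
  |ROI-mean ξ error| excluded vs raw.
- Steiger calibration: 5000 trivariate-normal draws at n = 30; BCa
  coverage: 500 replicates × 999 draws at n = 30.
- End-to-end cohort: 12 subjects, one planted outlier, 1000 bootstrap
  draws.

## Known limitations

- Scalar (single-polarisation) physics; no incompressibility, no
  subzone decomposition, no multi-frequency support.
- The SPR weight's "percent variation" operating point is
  implementation-specific; only its monotone effect and limits are
  portable claims.
- The cohort generator controls marginal summaries and two planted
  associations; the full joint distribution of a real cohort is richer.
- Screening-based covariate selection is data-dependent; downstream
  partial-correlation p-values are conditional on the selection, as in
  the emulated workflow.
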
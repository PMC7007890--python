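# hippomre

Desk-scale magnetic resonance elastography (MRE) of the hippocampus: a
self-contained Python re-implementation of the computational chain used to
relate regional brain viscoelasticity to episodic-memory performance in
small ageing cohorts.

MRE drives gentle shear waves into the head at a fixed actuation frequency
(50 Hz here) and images the resulting complex displacement field. Inverting
a viscoelastic wave model for the complex shear modulus
G\* = G′ + iG″ yields two voxelwise tissue descriptors:

- **damping ratio** ξ = G″ / 2G′ — the relative viscous-to-elastic
  behaviour (higher ξ: more fluid-like, interpreted as reduced
  microstructural integrity), and
- **shear stiffness** μ = 2|G\*|² / (|G\*| + G′) — the effective stiffness
  governing the shear-wave phase speed (μ = ρc²).

Because no subject-level data from such studies are public, the package
ships a first-class synthetic-data layer — voxel phantoms with known
viscoelastic ground truth, fluid (CSF-like) contamination, and simulated
subject cohorts with a controlled score/property joint structure — so that
every stage of the pipeline is testable end to end:

| stage | module | what it does |
|---|---|---|
| phantoms | `hippomre.phantom` | rasterised G′/G″ fields with hippocampus-like inclusions, CSF partial-volume maps |
| cohorts | `hippomre.cohort` | 11–12-subject tables (age, sex, IQ, integer memory score, regional ξ/μ/volume, eTIV) |
| forward model | `hippomre.forward` | time-harmonic scalar viscoelastic Helmholtz solver, ∇·(G\*∇u) + ρω²u = 0 |
| inversion | `hippomre.inversion` | nonlinear inversion (adjoint gradients, bounded quasi-Newton) with soft-prior regularization (SPR) over ROI masks and boundary-aware Gaussian smoothing |
| quality control | `hippomre.quality` | octahedral-shear-strain SNR (OSS-SNR) gating |
| ROI pipeline | `hippomre.roi` | affine mask transfer with 95% occupancy threshold, strict 0%-CSF exclusion, ξ/μ maps, regional summaries, eTIV volume normalisation |
| statistics | `hippomre.stats` | MAD outlier exclusion, \|S\|/\|K\| normality gating, covariate screening, partial Spearman correlations, Steiger's z for dependent correlations, BCa bootstrap CIs, Mann-Whitney / Wilcoxon tests |

NIfTI volumes (via nibabel), CSV cohort tables and YAML specs are the
on-disk formats; a `hippomre` CLI exposes each stage
(`phantom`, `cohort`, `simulate`, `invert`, `qc`, `roi`, `stats`).

## Worked example

Recover the viscoelasticity of a hippocampus-like inclusion from noisy
simulated wave data, then run the cohort analysis on a simulated study:

```python
from hippomre.experiments import two_region_recovery, end_to_end_cohort

rec = two_region_recovery(seed=0)
print(f"true  inclusion: xi = {rec.xi_true:.3f}, mu = {rec.mu_true/1000:.2f} kPa")
print(f"recovered (ROI): xi = {rec.xi_est:.3f}, mu = {rec.mu_est/1000:.2f} kPa")

rep = end_to_end_cohort(seed=0)
print(f"excluded subjects: {rep.excluded_ids}  (n = {rep.n_analytic} analytic)")
print(f"retained covariates: {rep.retained_covariates}")
row = rep.partial_correlations.loc["left_xi"]
print(f"left HC xi vs memory: r_s[{int(row['df'])}] = {row['r_s']:.2f}, p = {row['p']:.3f}")
```

prints

```
true  inclusion: xi = 0.180, mu = 3.01 kPa
recovered (ROI): xi = 0.177, mu = 3.02 kPa
excluded subjects: ['S001']  (n = 11 analytic)
retained covariates: ['age_years']
left HC xi vs memory: r_s[8] = -0.94, p = 0.000
```

The first block shows the inversion recovering the inclusion's damping
ratio and stiffness to within a few percent from data carrying 1%
measurement noise (simulated on a finer grid than the inversion mesh, with
SPR applied to the inclusion mask). The second block shows the cohort
pipeline excluding the one planted low scorer by the 3×MAD rule, retaining
age as the only screened covariate, and detecting the planted negative
association between left-hippocampal damping ratio and memory score as a
partial Spearman correlation with 8 residual degrees of freedom.

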
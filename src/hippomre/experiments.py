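"""Canonical verification experiments at desk scale.

Each function runs one self-contained study-condition experiment — fixed
phantom geometry, noise level and problem size — and returns the measured
quantities.  The test battery asserts on these results and the
``scripts/acceptance.py`` entry point re-reports them, so the experimental
conditions live in exactly one place.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cohort import CohortSpec, simulate_cohort
from .fields import ComplexModulusField
from .forward import (
    ForwardConfig,
    add_noise,
    complex_wavenumber,
    fit_attenuation,
    fit_wavelength,
    restrict_field,
    solve_time_harmonic,
)
from .inversion import InversionConfig, invert
from .phantom import CsfRegion, Inclusion, PhantomSpec, make_phantom
from .roi import RegionMaskSet, derived_maps, exclude_csf
from .stats import SteigerInput, bootstrap_ci, run_cohort_analysis, steiger_z

__all__ = [
    "homogeneous_wave_errors",
    "two_region_recovery",
    "csf_bias_experiment",
    "steiger_type_i_rate",
    "bca_coverage",
    "end_to_end_cohort",
]

RHO = 1000.0
FREQ = 50.0


def homogeneous_wave_errors(n: int = 128) -> dict[str, float]:
    """Relative errors of the solver against plane-wave closed forms.

    Elastic case: spatial wavelength vs f*lambda = sqrt(mu/rho).
    Viscoelastic case: fitted log-amplitude decay vs Im k of
    k = omega sqrt(rho/G*).
    """
    elastic = ComplexModulusField(np.full((n, n), 2000.0), np.zeros((n, n)), 1.6)
    field = solve_time_harmonic(elastic, ForwardConfig())
    lam = fit_wavelength(field)
    lam_th = np.sqrt(2000.0 / RHO) / FREQ
    wavelength_err = abs(lam - lam_th) / lam_th

    visco = ComplexModulusField(np.full((n, n), 2000.0), np.full((n, n), 700.0), 1.6)
    field_v = solve_time_harmonic(visco, ForwardConfig())
    k = complex_wavenumber(2000.0 + 700.0j, RHO, FREQ)
    alpha = fit_attenuation(field_v)
    attenuation_err = abs(alpha - k.imag) / k.imag
    return {
        "wavelength_rel_err": float(wavelength_err),
        "attenuation_rel_err": float(attenuation_err),
    }


@dataclass
class RecoveryResult:
    xi_rel_err: float
    mu_rel_err: float
    xi_true: float
    mu_true: float
    xi_est: float
    mu_est: float
    objective_history: list[float]
    roi_cv_gp: float


def _reference_spec(grid_shape, voxel_size_mm):
    center = tuple((s - 1) / 2 for s in grid_shape)
    return PhantomSpec(
        grid_shape=grid_shape,
        voxel_size_mm=voxel_size_mm,
        inclusions=[Inclusion(center, 8.0, 2750.0, 990.0, "hippocampus")],
    )


def two_region_recovery(
    seed: int = 0,
    noise_frac: float = 0.01,
    max_global_iters: int = 40,
    spr_weight: float = 1e-10,
) -> RecoveryResult:
    """Recover inclusion damping ratio and stiffness from noisy wave data.

    Two-region phantom (cerebrum-like background, hippocampus-like 8 mm
    inclusion) at 1.6 mm voxels; data simulated on a 2x finer grid from two
    orthogonal drive faces and subsampled to the inversion grid (no inverse
    crime), with Gaussian noise at ``noise_frac`` of the RMS amplitude; SPR
    on the inclusion mask.
    """
    props_fine, _ = make_phantom(_reference_spec((79, 79), 0.8))
    _, masks = make_phantom(_reference_spec((40, 40), 1.6))
    experiments = [ForwardConfig(drive_axis=0), ForwardConfig(drive_axis=1)]
    fields = []
    for i, exp in enumerate(experiments):
        f = restrict_field(solve_time_harmonic(props_fine, exp), 2)
        rms = float(np.sqrt(np.mean(np.abs(f.u) ** 2)))
        fields.append(add_noise(f, noise_frac * rms, seed=seed * 1000 + i))
    cfg = InversionConfig(
        experiments=experiments,
        spr_regions=["hippocampus"],
        spr_weight=spr_weight,
        max_global_iters=max_global_iters,
        seed=seed,
    )
    res = invert(fields, masks, cfg)
    roi = masks.masks["hippocampus"] > 0
    gp_m = float(res.estimate.gp[roi].mean())
    gpp_m = float(res.estimate.gpp[roi].mean())
    xi_est = gpp_m / (2 * gp_m)
    gabs = float(np.hypot(gp_m, gpp_m))
    mu_est = 2 * gabs**2 / (gabs + gp_m)
    xi_true = 990.0 / (2 * 2750.0)
    gabs_t = float(np.hypot(2750.0, 990.0))
    mu_true = 2 * gabs_t**2 / (gabs_t + 2750.0)
    return RecoveryResult(
        xi_rel_err=abs(xi_est - xi_true) / xi_true,
        mu_rel_err=abs(mu_est - mu_true) / mu_true,
        xi_true=xi_true,
        mu_true=mu_true,
        xi_est=xi_est,
        mu_est=mu_est,
        objective_history=res.objective_history,
        roi_cv_gp=float(res.estimate.gp[roi].std() / gp_m),
    )


def csf_bias_experiment(
    n_seeds: int = 20,
    base_seed: int = 0,
    max_global_iters: int = 12,
    noise_frac: float = 0.01,
) -> dict[str, object]:
    """Fluid-contaminated ROI borders: raw vs CSF-excluded summary bias.

    For each seed a fluid (CSF-like) sphere touches the hippocampus-like
    inclusion border at a random angle; the inversion applies SPR to the
    CSF-excluded mask only.  The per-seed absolute error of the ROI-mean
    damping ratio is compared between the raw and the CSF-excluded mask; a
    two-sided sign test summarises how often exclusion wins.
    """
    from scipy import stats as sps

    wins = 0
    errs_raw, errs_exc = [], []
    xi_true = 0.18
    n = 40
    c = (n - 1) / 2
    for s in range(n_seeds):
        rng = np.random.default_rng(base_seed + s)
        ang = rng.uniform(0, 2 * np.pi)
        r_off = (8.0 + 2.0) / 1.6
        csf_center = (c + r_off * np.cos(ang), c + r_off * np.sin(ang))
        spec = PhantomSpec(
            grid_shape=(n, n),
            inclusions=[Inclusion((c, c), 8.0, 2750.0, 990.0, "hippocampus")],
            csf_regions=[CsfRegion(csf_center, 4.0, feather_mm=2.4)],
        )
        props, masks = make_phantom(spec)
        experiments = [ForwardConfig(drive_axis=0), ForwardConfig(drive_axis=1)]
        fields = []
        for i, exp in enumerate(experiments):
            f = solve_time_harmonic(props, exp)
            rms = float(np.sqrt(np.mean(np.abs(f.u) ** 2)))
            fields.append(
                add_noise(f, noise_frac * rms, seed=(base_seed + s) * 1000 + i)
            )
        raw = masks.masks["hippocampus"]
        cleaned, _ = exclude_csf(raw, masks.csf_pv)
        inv_masks = RegionMaskSet(
            masks={"hippocampus": cleaned},
            csf_pv=masks.csf_pv,
            spacing_mm=1.6,
        )
        cfg = InversionConfig(
            experiments=experiments,
            spr_regions=["hippocampus"],
            max_global_iters=max_global_iters,
        )
        res = invert(fields, inv_masks, cfg)
        maps = derived_maps(res.estimate)
        err_raw = abs(float(maps.xi[raw > 0].mean()) - xi_true)
        err_exc = abs(float(maps.xi[cleaned > 0].mean()) - xi_true)
        errs_raw.append(err_raw)
        errs_exc.append(err_exc)
        wins += err_exc < err_raw
    sign_p = float(sps.binomtest(wins, n_seeds, 0.5).pvalue)
    return {
        "n_seeds": n_seeds,
        "wins": int(wins),
        "sign_test_p": sign_p,
        "mean_err_raw": float(np.mean(errs_raw)),
        "mean_err_excluded": float(np.mean(errs_exc)),
    }


def steiger_type_i_rate(
    n_sims: int = 5000, n: int = 30, seed: int = 0
) -> float:
    """Empirical type-I error of Steiger's test at |Z| > 1.96.

    Trivariate normal null with equal true correlations of the shared
    variable (0.4/0.4) and cross-correlation 0.5.
    """
    rng = np.random.default_rng(seed)
    corr = np.array([[1.0, 0.4, 0.4], [0.4, 1.0, 0.5], [0.4, 0.5, 1.0]])
    chol = np.linalg.cholesky(corr)
    x = rng.standard_normal((n_sims, n, 3)) @ chol.T
    xc = x - x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1)

    def pair(i, j):
        return (xc[:, :, i] * xc[:, :, j]).mean(axis=1) / (sd[:, i] * sd[:, j])

    r_jk, r_jh, r_kh = pair(0, 1), pair(0, 2), pair(1, 2)
    rejections = 0
    for a, b, c in zip(r_jk, r_jh, r_kh):
        z = steiger_z(SteigerInput(float(a), float(b), float(c), n)).coefficient
        rejections += abs(z) > 1.96
    return rejections / n_sims


def bca_coverage(
    n_replicates: int = 500,
    n: int = 30,
    n_boot: int = 999,
    rho: float = 0.5,
    seed: int = 0,
) -> float:
    """Coverage of the 95% BCa interval for the Spearman correlation.

    Bivariate normal samples with Pearson rho; the population Spearman
    value is (6/pi) asin(rho/2).
    """
    rho_s = 6.0 / np.pi * np.arcsin(rho / 2.0)
    rng = np.random.default_rng(seed)
    covered = 0
    for _ in range(n_replicates):
        z = rng.standard_normal((n, 2))
        x = z[:, 0]
        y = rho * z[:, 0] + np.sqrt(1 - rho**2) * z[:, 1]
        lo, hi = bootstrap_ci(
            x, y, n_boot=n_boot, seed=int(rng.integers(2**31))
        )
        covered += lo <= rho_s <= hi
    return covered / n_replicates


def end_to_end_cohort(seed: int = 0, n_boot: int = 1000):
    """Full pipeline on a 12-subject cohort with planted effects.

    Strong negative left-hippocampal damping-ratio effect plus a dominant
    age effect on the memory score, one pathologically low scorer planted;
    returns the analysis report.
    """
    spec = CohortSpec(
        n_subjects=12,
        plant_outlier=True,
        effect_xi_left=-1.0,
        effect_age=-1.5,
        noise_sd=0.05,
        seed=seed,
    )
    cohort = simulate_cohort(spec)
    return run_cohort_analysis(cohort, n_boot=n_boot, seed=seed)
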
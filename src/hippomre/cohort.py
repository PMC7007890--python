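"""Synthetic cohorts with the joint structure of a small ageing-memory study.

Each simulated subject carries demographics (age, sex, premorbid IQ), an
integer verbal paired-associates (VPA) immediate-recall score out of 24,
regional hippocampal viscoelasticity (damping ratio xi, shear stiffness mu
in kPa, volume in cm^3, for left/right/bilateral), a global cerebral
reference damping ratio, head-size normalisation volume (eTIV) and an
OSS-SNR quality score.

The memory score is a monotone function of a latent trait driven by left
hippocampal damping ratio and age (standardised, with configurable
standardised effect sizes) plus Gaussian noise, discretised to integers.
Default effect sizes reproduce the observed association magnitudes in the
emulated study population: Spearman(score, left xi) ~ -0.77 and
Spearman(score, age) ~ -0.60.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["CohortSpec", "simulate_cohort", "COHORT_COLUMNS"]

#: Regional property marginals (mean, SD) emulated by the generator:
#: damping ratio (dimensionless), stiffness (kPa), volume (cm^3).
DEFAULT_REGIONAL_PARAMS: dict[str, tuple[float, float]] = {
    "left_xi": (0.162, 0.052),
    "right_xi": (0.186, 0.038),
    "left_mu": (2.77, 0.51),
    "right_mu": (2.91, 0.40),
    "left_vol": (4.02, 0.66),
    "right_vol": (4.17, 0.53),
    "global_xi": (0.17, 0.02),
    "iq": (123.4, 4.25),
    "etiv": (1450.0, 120.0),
    "oss_snr": (5.79, 1.54),
}

COHORT_COLUMNS = [
    "id",
    "age_years",
    "sex",
    "iq_score",
    "memory_score",
    "left_xi",
    "right_xi",
    "bilateral_xi",
    "left_mu",
    "right_mu",
    "bilateral_mu",
    "left_vol",
    "right_vol",
    "bilateral_vol",
    "global_xi",
    "etiv",
    "oss_snr",
]


@dataclass
class CohortSpec:
    """Generative description of a synthetic cohort.

    ``effect_xi_left`` and ``effect_age`` are standardised slopes of the
    latent memory trait on left-hippocampal damping ratio and age;
    ``noise_sd`` is the residual SD on the same standardised scale.  The
    default triple (-0.77, -0.60, 0.22) targets the emulated study's
    association magnitudes.  ``plant_outlier`` forces the first subject to a
    pathologically low recall score (clinical-range), for testing the
    outlier-exclusion stage.
    """

    n_subjects: int = 11
    age_range_years: tuple[int, int] = (66, 72)
    sex_ratio: float = 0.55  # probability of female
    score_mean: float = 20.7
    score_sd: float = 1.95
    score_range: tuple[int, int] = (17, 24)
    max_score: int = 24
    effect_xi_left: float = -0.77
    effect_age: float = -0.60
    noise_sd: float = 0.22
    lr_correlation: float = 0.5
    regional_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_REGIONAL_PARAMS)
    )
    plant_outlier: bool = False
    outlier_score: int = 11
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 4:
            raise ValueError("n_subjects must be >= 4")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.sex_ratio <= 1:
            raise ValueError("sex_ratio must lie in [0, 1]")
        if self.age_range_years[0] > self.age_range_years[1]:
            raise ValueError("age range is inverted")
        xi_sd = self.regional_params["left_xi"][1]
        age_span = self.age_range_years[1] - self.age_range_years[0]
        if (
            self.noise_sd == 0
            and ((self.effect_xi_left != 0 and xi_sd == 0)
                 or (self.effect_age != 0 and age_span == 0))
        ):
            raise ValueError(
                "degenerate spec: nonzero effects on zero-variance predictors"
            )


def _correlated_pair(
    rng: np.random.Generator,
    n: int,
    p1: tuple[float, float],
    p2: tuple[float, float],
    rho: float,
    lo: float,
) -> tuple[np.ndarray, np.ndarray]:
    z = rng.multivariate_normal(
        [0.0, 0.0], [[1.0, rho], [rho, 1.0]], size=n
    )
    a = np.clip(p1[0] + p1[1] * z[:, 0], lo, None)
    b = np.clip(p2[0] + p2[1] * z[:, 1], lo, None)
    return a, b


def simulate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw one cohort table; bit-identical for identical spec and seed.

    Bilateral quantities are consistent aggregates of the unilateral ones:
    volume is the sum, damping ratio and stiffness are volume-weighted
    means.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    rp = spec.regional_params

    # ages cover the recruitment range evenly (shuffled grid), as in a
    # cohort recruited across an age band rather than sampled iid
    lo, hi = spec.age_range_years
    age = np.round(np.linspace(lo, hi, n)).astype(float)
    rng.shuffle(age)
    sex = np.where(rng.random(n) < spec.sex_ratio, "F", "M")
    iq = np.round(rng.normal(*rp["iq"], size=n))

    lxi, rxi = _correlated_pair(rng, n, rp["left_xi"], rp["right_xi"], spec.lr_correlation, 0.02)
    lmu, rmu = _correlated_pair(rng, n, rp["left_mu"], rp["right_mu"], spec.lr_correlation, 0.5)
    lvol, rvol = _correlated_pair(rng, n, rp["left_vol"], rp["right_vol"], 0.7, 1.0)
    gxi = np.clip(rng.normal(*rp["global_xi"], size=n), 0.02, None)
    bvol = lvol + rvol
    bxi = (lvol * lxi + rvol * rxi) / bvol
    bmu = (lvol * lmu + rvol * rmu) / bvol
    etiv = np.maximum(rng.normal(*rp["etiv"], size=n), bvol + 100.0)
    oss = np.clip(rng.normal(*rp["oss_snr"], size=n), 1.0, None)

    # latent memory trait: sample-standardised predictors so the realised
    # score spread matches the nominal score SD for every draw (clustered
    # predictor draws would otherwise collapse the integer scores into ties)
    def _z(v: np.ndarray) -> np.ndarray:
        sd = v.std()
        return (v - v.mean()) / sd if sd > 0 else np.zeros_like(v)

    latent = (
        spec.effect_xi_left * _z(lxi)
        + spec.effect_age * _z(age)
        + spec.noise_sd * rng.standard_normal(n)
    )
    latent_sd = latent.std()
    latent_std = latent / latent_sd if latent_sd > 0 else np.zeros(n)
    score = np.clip(
        np.round(spec.score_mean + spec.score_sd * latent_std),
        max(spec.score_range[0], 0),
        min(spec.score_range[1], spec.max_score),
    ).astype(int)
    if spec.plant_outlier:
        score[0] = spec.outlier_score

    return pd.DataFrame(
        {
            "id": [f"S{i + 1:03d}" for i in range(n)],
            "age_years": age,
            "sex": sex,
            "iq_score": iq,
            "memory_score": score,
            "left_xi": lxi,
            "right_xi": rxi,
            "bilateral_xi": bxi,
            "left_mu": lmu,
            "right_mu": rmu,
            "bilateral_mu": bmu,
            "left_vol": lvol,
            "right_vol": rvol,
            "bilateral_vol": bvol,
            "global_xi": gxi,
            "etiv": etiv,
            "oss_snr": oss,
        },
        columns=COHORT_COLUMNS,
    )
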
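"""Cohort statistics for small-sample structure-function analyses.

The inference chain mirrors the conservative small-n workflow used for
regional viscoelasticity vs. memory-score analyses:

1. robust outlier exclusion on the behavioural score (median absolute
   deviation, 3 x scaled MAD);
2. normality screening of every variable via standardised skewness and
   kurtosis (|S| or |K| > 1.96 mandates nonparametric tests);
3. univariate covariate screening (Spearman; Mann-Whitney for sex),
   retaining only covariates associated with the score at p <= 0.05;
4. partial Spearman correlations of each regional measure with the score,
   controlling for the retained covariates (t approximation,
   df = n - 2 - k);
5. Steiger's z for the difference between dependent correlations sharing
   the score, and BCa bootstrap confidence intervals;
6. Wilcoxon signed-rank tests for hemispheric differences.

No multiple-testing correction is applied (the report counts the
uncorrected tests instead), matching the exploratory design the module
emulates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "OutlierReport",
    "NormalityReport",
    "StatResult",
    "SteigerInput",
    "mad_outliers",
    "normality_indices",
    "spearman_partial",
    "steiger_z",
    "normal_p_two_tailed",
    "normal_critical_value",
    "partial_p_from_r",
    "bootstrap_ci",
    "spearman_statistic",
    "mann_whitney_u",
    "wilcoxon_signed_rank",
    "run_cohort_analysis",
    "CohortReport",
]

#: Consistency constant making the MAD estimate the SD of a normal sample.
MAD_SCALE = 1.4826


# ---------------------------------------------------------------------------
# result containers


@dataclass
class OutlierReport:
    median: float
    mad_scaled: float
    criterion: float
    flags: np.ndarray
    degenerate: bool = False


@dataclass
class NormalityReport:
    skewness: float
    kurtosis: float
    se_skew: float
    se_kurt: float
    s_index: float
    k_index: float
    nonparametric_required: bool


@dataclass
class StatResult:
    method: str
    coefficient: float
    df: int | None
    p_two_tailed: float
    ci_low: float | None = None
    ci_high: float | None = None
    n: int | None = None
    covariates: tuple[str, ...] = ()
    extra: dict = dc_field(default_factory=dict)


@dataclass
class SteigerInput:
    """Correlations for comparing r_jk with r_jh (j shared), plus r_kh."""

    r_jk: float
    r_jh: float
    r_kh: float
    n: int

    def validate(self) -> None:
        for r in (self.r_jk, self.r_jh, self.r_kh):
            if not -1 <= r <= 1:
                raise ValueError("correlations must lie in [-1, 1]")
        if abs(self.r_jk) == 1 or abs(self.r_jh) == 1:
            raise ValueError("|r| = 1: Fisher transform undefined")
        if self.n < 4:
            raise ValueError("n must be >= 4")
        corr = np.array(
            [
                [1.0, self.r_jk, self.r_jh],
                [self.r_jk, 1.0, self.r_kh],
                [self.r_jh, self.r_kh, 1.0],
            ]
        )
        if np.linalg.eigvalsh(corr).min() < -1e-10:
            warnings.warn("implied 3x3 correlation matrix is not positive semi-definite")


# ---------------------------------------------------------------------------
# robust screening


def mad_outliers(x: Sequence[float], criterion: float = 3.0) -> OutlierReport:
    """Flag observations deviating from the median by > criterion x scaled MAD.

    The MAD is scaled by 1.4826 for consistency with the normal SD.  A zero
    MAD (more than half the sample at the median) is degenerate: every
    off-median point is flagged and a warning is emitted.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    med = float(np.median(x))
    mad = MAD_SCALE * float(np.median(np.abs(x - med)))
    if mad == 0:
        flags = x != med
        if flags.any():
            warnings.warn("zero MAD: flagging every observation off the median")
        return OutlierReport(med, 0.0, criterion, flags, degenerate=True)
    flags = np.abs(x - med) > criterion * mad
    return OutlierReport(med, mad, criterion, flags)


def normality_indices(x: Sequence[float]) -> NormalityReport:
    """Standardised skewness and kurtosis indices S and K.

    Uses the adjusted Fisher-Pearson sample skewness and excess kurtosis
    with their large-sample standard errors; |S| or |K| above 1.96 flags a
    significant departure from normality at p < 0.05.
    """
    x = np.asarray(x, dtype=float)
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    skew = float(sps.skew(x, bias=False))
    kurt = float(sps.kurtosis(x, bias=False))
    se_skew = float(np.sqrt(6.0 * n * (n - 1) / ((n - 2) * (n + 1) * (n + 3))))
    se_kurt = float(2.0 * se_skew * np.sqrt((n**2 - 1) / ((n - 3) * (n + 5))))
    s_index = skew / se_skew
    k_index = kurt / se_kurt
    return NormalityReport(
        skewness=skew,
        kurtosis=kurt,
        se_skew=se_skew,
        se_kurt=se_kurt,
        s_index=s_index,
        k_index=k_index,
        nonparametric_required=(abs(s_index) > 1.96 or abs(k_index) > 1.96),
    )


# ---------------------------------------------------------------------------
# correlations


def _rank(a: np.ndarray) -> np.ndarray:
    return sps.rankdata(a, method="average")


def spearman_partial(
    x: Sequence[float],
    y: Sequence[float],
    covariates: np.ndarray | Sequence[Sequence[float]] | None = None,
    covariate_names: tuple[str, ...] = (),
) -> StatResult:
    """Partial Spearman correlation of x and y given covariates.

    All variables (including covariates) are rank-transformed with average
    ranks for ties; the Pearson partial correlation of the ranked x and y
    given the ranked covariates is computed via double residualisation.  The
    two-tailed p-value uses the t approximation with df = n - 2 - k.  With
    no covariates this reduces to the ordinary Spearman coefficient.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if y.size != n:
        raise ValueError("x and y lengths differ")
    if covariates is None:
        cov = np.empty((n, 0))
    else:
        cov = np.atleast_2d(np.asarray(covariates, dtype=float))
        if cov.shape[0] != n:
            cov = cov.T
        if cov.shape[0] != n:
            raise ValueError("covariate length mismatch")
    k = cov.shape[1]
    if n < k + 4:
        raise ValueError(f"need n >= k + 4 (n={n}, k={k})")

    rx = _rank(x)
    ry = _rank(y)
    design = np.column_stack([np.ones(n)] + [_rank(cov[:, j]) for j in range(k)])
    bx, *_ = np.linalg.lstsq(design, rx, rcond=None)
    by, *_ = np.linalg.lstsq(design, ry, rcond=None)
    ex = rx - design @ bx
    ey = ry - design @ by
    sx, sy = np.linalg.norm(ex), np.linalg.norm(ey)
    tiny = 1e-10 * np.sqrt(n)
    if sx < tiny or sy < tiny:
        raise ValueError("zero residual variance; partial correlation undefined")
    r = float(np.clip(ex @ ey / (sx * sy), -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return StatResult(
        method="spearman_partial" if k else "spearman",
        coefficient=r,
        df=df,
        p_two_tailed=p,
        n=n,
        covariates=covariate_names,
    )


def normal_p_two_tailed(z: float) -> float:
    """p = 2 (1 - Phi(|z|)); the conventional two-tailed normal p-value."""
    if not np.isfinite(z):
        raise ValueError("z must be finite")
    return float(2.0 * sps.norm.sf(abs(z)))


def normal_critical_value(alpha: float = 0.05) -> float:
    """Two-sided standard-normal critical value (1.96 at alpha = 0.05)."""
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    return float(sps.norm.ppf(1.0 - alpha / 2.0))


def partial_p_from_r(r: float, df: int) -> float:
    """Two-tailed p for a (partial) correlation via the t approximation.

    t = r sqrt(df / (1 - r^2)) with df = n - 2 - k residual degrees of
    freedom; the same conversion :func:`spearman_partial` applies.
    """
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    if df < 1:
        raise ValueError("df must be >= 1")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt(df / (1.0 - r**2))
    return float(2.0 * sps.t.sf(abs(t), df))


def steiger_z(inp: SteigerInput) -> StatResult:
    """Steiger's test for two dependent correlations sharing one variable.

    Fisher-transforms r_jk and r_jh and standardises their difference using
    the pooled-mean-correlation covariance term

        psi = r_kh (1 - 2 rbar^2) - rbar^2 (1 - 2 rbar^2 - r_kh^2) / 2,
        s   = psi / (1 - rbar^2)^2,
        Z   = (z_jk - z_jh) sqrt( (n - 3) / (2 - 2 s) ).
    """
    inp.validate()
    z_jk = np.arctanh(inp.r_jk)
    z_jh = np.arctanh(inp.r_jh)
    rbar = 0.5 * (inp.r_jk + inp.r_jh)
    rb2 = rbar**2
    psi = inp.r_kh * (1.0 - 2.0 * rb2) - 0.5 * rb2 * (1.0 - 2.0 * rb2 - inp.r_kh**2)
    s = psi / (1.0 - rb2) ** 2
    z_stat = float((z_jk - z_jh) * np.sqrt((inp.n - 3) / (2.0 - 2.0 * s)))
    return StatResult(
        method="steiger_z",
        coefficient=z_stat,
        df=None,
        p_two_tailed=normal_p_two_tailed(z_stat),
        n=inp.n,
        extra={"r_jk": inp.r_jk, "r_jh": inp.r_jh, "r_kh": inp.r_kh},
    )


# ---------------------------------------------------------------------------
# bootstrap


def spearman_statistic(x: np.ndarray, y: np.ndarray, axis: int = -1) -> np.ndarray:
    """Vectorised Spearman correlation along an axis (for bootstrap use)."""
    rx = sps.rankdata(x, axis=axis)
    ry = sps.rankdata(y, axis=axis)
    rx = rx - rx.mean(axis=axis, keepdims=True)
    ry = ry - ry.mean(axis=axis, keepdims=True)
    num = (rx * ry).sum(axis=axis)
    den = np.sqrt((rx**2).sum(axis=axis) * (ry**2).sum(axis=axis))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bootstrap_ci(
    x: Sequence[float],
    y: Sequence[float] | None,
    statistic: Callable[..., np.ndarray] = spearman_statistic,
    n_boot: int = 1000,
    level: float = 0.95,
    method: str = "BCa",
    seed: int = 0,
) -> tuple[float, float]:
    """Paired bootstrap confidence interval, bias-corrected and accelerated.

    Resamples subject rows with replacement (pairs stay together), applying
    ``statistic`` (vectorised along the last axis) to each resample.  The
    BCa endpoints use the bias-correction term z0 (normal quantile of the
    proportion of bootstrap statistics below the point estimate) and the
    jackknife-skewness acceleration a.  ``method="percentile"`` skips both
    corrections.  Deterministic given ``seed``.

    Resamples on which the statistic is undefined (e.g. a constant vector
    under Spearman) are dropped; if every resample is degenerate the
    interval collapses to the point estimate when the data admit no
    variability, otherwise an error is raised.
    """
    x = np.asarray(x, dtype=float)
    arrays = [x] if y is None else [x, np.asarray(y, dtype=float)]
    n = x.size
    if n < 5:
        raise ValueError("need at least 5 observations")
    if any(a.size != n for a in arrays):
        raise ValueError("paired vectors must have equal length")
    if method not in ("BCa", "percentile"):
        raise ValueError("method must be 'BCa' or 'percentile'")
    observed = float(np.asarray(statistic(*arrays, axis=-1)))

    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(n_boot, n))
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.asarray(statistic(*[a[idx] for a in arrays], axis=-1), dtype=float)
    finite = dist[np.isfinite(dist)]
    if finite.size == 0:
        raise ValueError("statistic degenerate on all bootstrap resamples")
    if np.ptp(finite) == 0 and np.isclose(finite[0], observed):
        return observed, observed

    alpha = (1.0 - level) / 2.0
    if method == "percentile":
        return (
            float(np.quantile(finite, alpha)),
            float(np.quantile(finite, 1.0 - alpha)),
        )

    # bias correction
    prop = np.mean(finite < observed) + 0.5 * np.mean(finite == observed)
    prop = np.clip(prop, 1.0 / (finite.size + 1), finite.size / (finite.size + 1.0))
    z0 = sps.norm.ppf(prop)
    # acceleration from the jackknife
    jack = np.empty(n)
    keep = np.ones(n, dtype=bool)
    with np.errstate(invalid="ignore", divide="ignore"):
        for i in range(n):
            keep[i] = False
            jack[i] = float(
                np.asarray(statistic(*[a[keep] for a in arrays], axis=-1))
            )
            keep[i] = True
    jack = jack[np.isfinite(jack)]
    d = jack.mean() - jack
    denom = 6.0 * (d @ d) ** 1.5
    a_hat = float((d**3).sum() / denom) if denom > 0 else 0.0

    z_lo, z_hi = sps.norm.ppf([alpha, 1.0 - alpha])
    q_lo = sps.norm.cdf(z0 + (z0 + z_lo) / (1.0 - a_hat * (z0 + z_lo)))
    q_hi = sps.norm.cdf(z0 + (z0 + z_hi) / (1.0 - a_hat * (z0 + z_hi)))
    return (
        float(np.quantile(finite, q_lo)),
        float(np.quantile(finite, q_hi)),
    )


# ---------------------------------------------------------------------------
# rank tests


def mann_whitney_u(x_a: Sequence[float], x_b: Sequence[float]) -> StatResult:
    """Two-sided Mann-Whitney U test with a standardised z coefficient.

    ``coefficient`` is the tie-corrected, continuity-corrected normal
    deviate of U (the convention small-sample neuro studies print); the raw
    U statistic for group A is kept in ``extra``.
    """
    a = np.asarray(x_a, dtype=float)
    b = np.asarray(x_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    u = float(res.statistic)
    n1, n2 = a.size, b.size
    mean_u = n1 * n2 / 2.0
    combined = np.concatenate([a, b])
    _, counts = np.unique(combined, return_counts=True)
    n = n1 + n2
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var_u <= 0:
        z = 0.0
    else:
        z = (u - mean_u - 0.5 * np.sign(u - mean_u)) / np.sqrt(var_u)
    return StatResult(
        method="mann_whitney_u",
        coefficient=float(z),
        df=None,
        p_two_tailed=float(res.pvalue),
        n=n,
        extra={"U": u},
    )


def wilcoxon_signed_rank(
    paired_a: Sequence[float], paired_b: Sequence[float]
) -> StatResult:
    """Two-sided Wilcoxon signed-rank test reporting the standardised z."""
    a = np.asarray(paired_a, dtype=float)
    b = np.asarray(paired_b, dtype=float)
    if a.size != b.size:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    if np.all(d == 0):
        raise ValueError("all paired differences are zero; test undefined")
    res = sps.wilcoxon(a, b, correction=True, method="approx")
    return StatResult(
        method="wilcoxon_signed_rank",
        coefficient=float(res.zstatistic),
        df=None,
        p_two_tailed=float(res.pvalue),
        n=int(a.size),
        extra={"W": float(res.statistic)},
    )


# ---------------------------------------------------------------------------
# full pipeline


REGIONAL_MEASURES = [
    "left_xi",
    "right_xi",
    "bilateral_xi",
    "left_mu",
    "right_mu",
    "bilateral_mu",
    "left_vol",
    "right_vol",
    "bilateral_vol",
]

SCREEN_COVARIATES = ["age_years", "sex", "iq_score", "bilateral_vol"]


@dataclass
class CohortReport:
    n_initial: int
    excluded_ids: list[str]
    n_analytic: int
    normality: pd.DataFrame
    screening: pd.DataFrame
    retained_covariates: list[str]
    partial_correlations: pd.DataFrame
    steiger: list[StatResult]
    bootstrap_cis: dict[str, tuple[float, float]]
    wilcoxon: dict[str, StatResult]
    n_uncorrected_tests: int

    def to_dict(self) -> dict:
        """JSON-serialisable summary of the full analysis."""
        return {
            "n_initial": self.n_initial,
            "excluded_ids": self.excluded_ids,
            "n_analytic": self.n_analytic,
            "retained_covariates": self.retained_covariates,
            "normality": self.normality.to_dict(orient="index"),
            "screening": self.screening.to_dict(orient="index"),
            "partial_correlations": self.partial_correlations.to_dict(orient="index"),
            "steiger": [
                {"comparison": s.extra.get("comparison"), "z": s.coefficient,
                 "p": s.p_two_tailed}
                for s in self.steiger
            ],
            "bootstrap_cis": {k: list(v) for k, v in self.bootstrap_cis.items()},
            "wilcoxon": {
                k: {"z": v.coefficient, "p": v.p_two_tailed}
                for k, v in self.wilcoxon.items()
            },
            "n_uncorrected_tests": self.n_uncorrected_tests,
        }


def run_cohort_analysis(
    cohort: pd.DataFrame,
    mad_criterion: float = 3.0,
    screen_alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> CohortReport:
    """Execute the full cohort inference chain on a subject table.

    See the module docstring for the ordered stages.  Covariates are
    retained when their univariate association with the memory score reaches
    ``screen_alpha`` (inclusive), the parsimony rule appropriate for a
    cohort of ~11 subjects.  Raises if fewer than 8 subjects survive outlier
    exclusion.
    """
    required = {"memory_score", "age_years", "sex", "iq_score"} | set(REGIONAL_MEASURES)
    missing = required - set(cohort.columns)
    if missing:
        raise ValueError(f"cohort table is missing columns: {sorted(missing)}")

    n_initial = len(cohort)
    out = mad_outliers(cohort["memory_score"].to_numpy(), criterion=mad_criterion)
    excluded = cohort.loc[out.flags, "id"].tolist() if "id" in cohort else list(
        cohort.index[out.flags].astype(str)
    )
    data = cohort.loc[~out.flags].reset_index(drop=True)
    n = len(data)
    if n < 8:
        raise ValueError(f"only {n} subjects after outlier exclusion (need >= 8)")

    numeric_vars = ["age_years", "iq_score", "memory_score", "oss_snr"] + [
        c for c in REGIONAL_MEASURES + ["global_xi", "etiv"] if c in data
    ]
    normality = pd.DataFrame(
        {
            var: {
                "S": (rep := normality_indices(data[var].to_numpy())).s_index,
                "K": rep.k_index,
                "nonparametric": rep.nonparametric_required,
            }
            for var in numeric_vars
            if data[var].nunique() > 1
        }
    ).T

    # univariate covariate screening against score and regional measures
    deps = ["memory_score"] + [m for m in REGIONAL_MEASURES if m in data]
    screen_rows = {}
    for cov_name in SCREEN_COVARIATES:
        if cov_name not in data:
            continue
        row = {}
        for dep in deps:
            if cov_name == dep:
                row[dep] = (np.nan, np.nan)
                continue
            if cov_name == "sex":
                g_f = data.loc[data["sex"] == "F", dep].to_numpy()
                g_m = data.loc[data["sex"] == "M", dep].to_numpy()
                if g_f.size == 0 or g_m.size == 0:
                    row[dep] = (np.nan, np.nan)
                    continue
                r = mann_whitney_u(g_f, g_m)
            else:
                r = spearman_partial(data[cov_name].to_numpy(), data[dep].to_numpy())
            row[dep] = (r.coefficient, r.p_two_tailed)
        screen_rows[cov_name] = row
    screening = pd.DataFrame(
        {
            cov: {f"{dep}": f"{v[0]:.2f} (p={v[1]:.3f})" for dep, v in row.items()}
            for cov, row in screen_rows.items()
        }
    ).T

    retained = [
        cov
        for cov, row in screen_rows.items()
        if cov != "bilateral_vol"  # volume is a dependent measure, not a nuisance
        and np.isfinite(row["memory_score"][1])
        and row["memory_score"][1] <= screen_alpha
    ]
    cov_matrix = (
        np.column_stack(
            [
                (data[c] == "F").astype(float) if c == "sex" else data[c].to_numpy()
                for c in retained
            ]
        )
        if retained
        else None
    )

    score = data["memory_score"].to_numpy()
    pc_rows = {}
    for meas in deps[1:]:
        r = spearman_partial(
            data[meas].to_numpy(), score, cov_matrix, tuple(retained)
        )
        pc_rows[meas] = {
            "r_s": r.coefficient,
            "df": r.df,
            "p": r.p_two_tailed,
        }
    partial_correlations = pd.DataFrame(pc_rows).T

    # dependent-correlation comparisons sharing the memory score
    def _plain_rho(a: str, b: str) -> float:
        return spearman_partial(data[a].to_numpy(), data[b].to_numpy()).coefficient

    steiger_results = []
    comparisons = [("left_xi", "right_xi")]
    if "global_xi" in data:
        comparisons.append(("left_xi", "global_xi"))
    for va, vb in comparisons:
        inp = SteigerInput(
            r_jk=_plain_rho("memory_score", vb),
            r_jh=_plain_rho("memory_score", va),
            r_kh=_plain_rho(va, vb),
            n=n,
        )
        res = steiger_z(inp)
        res.extra["comparison"] = f"{va}_vs_{vb}"
        steiger_results.append(res)

    boot_cis = {}
    for i, meas in enumerate(["left_xi", "right_xi"] + (["global_xi"] if "global_xi" in data else [])):
        boot_cis[meas] = bootstrap_ci(
            data[meas].to_numpy(), score, n_boot=n_boot, seed=seed + i
        )

    wilcoxon_tests = {}
    for quantity in ("xi", "mu", "vol"):
        left = data[f"left_{quantity}"].to_numpy()
        right = data[f"right_{quantity}"].to_numpy()
        try:
            wilcoxon_tests[quantity] = wilcoxon_signed_rank(left, right)
        except ValueError:
            continue

    n_tests = (
        sum(sum(np.isfinite(v[1]) for v in row.values()) for row in screen_rows.values())
        + len(pc_rows)
        + len(steiger_results)
        + len(wilcoxon_tests)
    )

    return CohortReport(
        n_initial=n_initial,
        excluded_ids=excluded,
        n_analytic=n,
        normality=normality,
        screening=screening,
        retained_covariates=retained,
        partial_correlations=partial_correlations,
        steiger=steiger_results,
        bootstrap_cis=boot_cis,
        wilcoxon=wilcoxon_tests,
        n_uncorrected_tests=n_tests,
    )
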
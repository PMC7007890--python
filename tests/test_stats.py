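import numpy as np
import pytest
from scipy import stats as sps

from hippomre.cohort import CohortSpec, simulate_cohort
from hippomre.stats import (
    SteigerInput,
    bootstrap_ci,
    mad_outliers,
    mann_whitney_u,
    normal_critical_value,
    normal_p_two_tailed,
    normality_indices,
    partial_p_from_r,
    run_cohort_analysis,
    spearman_partial,
    spearman_statistic,
    steiger_z,
    wilcoxon_signed_rank,
)


# ---------------------------------------------------------------------------
# MAD outliers


def test_mad_flags_single_extreme_point():
    rep = mad_outliers([1, 2, 3, 4, 100])
    assert rep.median == 3 and rep.mad_scaled == pytest.approx(1.4826)
    np.testing.assert_array_equal(rep.flags, [False] * 4 + [True])


def test_mad_constant_vector_degenerate():
    rep = mad_outliers([5, 5, 5, 5])
    assert rep.degenerate and not rep.flags.any()


def test_mad_symmetric_sample_unflagged():
    rep = mad_outliers(list(range(1, 12)))
    assert not rep.flags.any()


def test_mad_zero_with_offmedian_warns():
    with pytest.warns(UserWarning, match="MAD"):
        rep = mad_outliers([5, 5, 5, 5, 9])
    assert rep.flags.tolist() == [False] * 4 + [True]


# ---------------------------------------------------------------------------
# normality indices


def test_standard_error_formulas_at_n_11():
    x = np.random.default_rng(0).normal(size=11)
    rep = normality_indices(x)
    assert rep.se_skew == pytest.approx(0.6607, abs=1e-4)
    assert rep.se_kurt == pytest.approx(1.2795, abs=1e-4)


def test_symmetric_sample_has_zero_skew_index():
    x = np.array([-3, -2, -1, 0, 1, 2, 3], dtype=float)
    rep = normality_indices(x)
    assert rep.s_index == pytest.approx(0.0, abs=1e-12)


def test_gating_threshold():
    """|S| just above 1.96 mandates nonparametric statistics."""
    rng = np.random.default_rng(4)
    for _ in range(200):
        x = rng.exponential(size=11)
        rep = normality_indices(x)
        if abs(rep.s_index) > 1.96:
            assert rep.nonparametric_required
            break
    else:
        pytest.fail("no skewed draw found")
    assert not normality_indices(np.arange(11.0)).nonparametric_required


def test_small_sample_raises():
    with pytest.raises(ValueError):
        normality_indices([1.0, 2.0, 3.0, 4.0])


# ---------------------------------------------------------------------------
# (partial) Spearman


def test_partial_p_value_anchor():
    assert partial_p_from_r(-0.77, 8) == pytest.approx(0.009, abs=5e-4)


def test_plain_spearman_matches_scipy():
    rng = np.random.default_rng(1)
    for _ in range(25):
        x = rng.normal(size=15)
        y = rng.normal(size=15) + 0.5 * x
        res = spearman_partial(x, y)
        ref = sps.spearmanr(x, y)
        assert res.coefficient == pytest.approx(ref.statistic, abs=1e-12)


def test_perfect_monotone_association():
    x = np.arange(10.0)
    res = spearman_partial(x, x**3)
    assert res.coefficient == pytest.approx(1.0)
    assert res.p_two_tailed == pytest.approx(0.0, abs=1e-12)


def test_partial_matches_pingouin_oracle():
    pingouin = pytest.importorskip("pingouin")
    import pandas as pd

    rng = np.random.default_rng(2)
    for trial in range(50):
        n = int(rng.integers(10, 25))
        z = rng.normal(size=n)
        x = 0.5 * z + rng.normal(size=n)
        y = -0.4 * z + rng.normal(size=n)
        res = spearman_partial(x, y, covariates=z[:, None])
        df = pd.DataFrame({"x": x, "y": y, "z": z})
        ref = pingouin.partial_corr(df, x="x", y="y", covar="z", method="spearman")
        p_col = "p_val" if "p_val" in ref.columns else "p-val"
        assert res.coefficient == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p_two_tailed == pytest.approx(float(ref[p_col].iloc[0]), abs=1e-6)


def test_partial_null_given_confounder_is_small():
    rng = np.random.default_rng(3)
    n = 2000
    z = rng.normal(size=n)
    x = z + rng.normal(size=n)
    y = z + rng.normal(size=n)  # x,y dependent only through z
    res = spearman_partial(x, y, covariates=z[:, None])
    assert abs(res.coefficient) < 0.05


def test_zero_residual_variance_raises():
    z = np.arange(10.0)
    with pytest.raises(ValueError, match="residual"):
        spearman_partial(z, np.ones(10), covariates=z[:, None])


# ---------------------------------------------------------------------------
# Steiger's z and normal p helpers


def test_equal_correlations_give_zero_z():
    res = steiger_z(SteigerInput(0.5, 0.5, 0.3, 20))
    assert res.coefficient == 0.0
    assert res.p_two_tailed == 1.0


def test_z_to_p_conversion_anchors():
    assert normal_p_two_tailed(1.98) == pytest.approx(0.048, abs=5e-4)
    assert normal_p_two_tailed(1.71) == pytest.approx(0.09, abs=5e-3)
    assert normal_p_two_tailed(0.0) == 1.0
    assert normal_critical_value(0.05) == pytest.approx(1.96, abs=5e-3)


def test_steiger_sign_and_antisymmetry():
    a = steiger_z(SteigerInput(0.7, 0.3, 0.4, 25))
    b = steiger_z(SteigerInput(0.3, 0.7, 0.4, 25))
    assert a.coefficient > 0 > b.coefficient
    assert a.coefficient == pytest.approx(-b.coefficient)
    assert a.p_two_tailed == pytest.approx(b.p_two_tailed)


def test_steiger_degenerate_inputs():
    with pytest.raises(ValueError, match="Fisher"):
        steiger_z(SteigerInput(1.0, 0.5, 0.3, 20))
    with pytest.warns(UserWarning, match="definite"):
        steiger_z(SteigerInput(0.9, -0.9, 0.9, 20))


# ---------------------------------------------------------------------------
# bootstrap


def test_constant_data_interval_collapses():
    lo, hi = bootstrap_ci(
        np.full(10, 3.0), None, statistic=lambda x, axis=-1: np.mean(x, axis=axis)
    )
    assert lo == hi == 3.0


def test_bootstrap_deterministic_given_seed():
    rng = np.random.default_rng(5)
    x, y = rng.normal(size=(2, 30))
    assert bootstrap_ci(x, y, seed=7) == bootstrap_ci(x, y, seed=7)
    assert bootstrap_ci(x, y, seed=7) != bootstrap_ci(x, y, seed=8)


def test_bca_agrees_with_scipy_reference():
    """Independent BCa route (scipy.stats.bootstrap) lands on near-identical endpoints."""
    rng = np.random.default_rng(6)
    z = rng.standard_normal((40, 2))
    x, y = z[:, 0], 0.6 * z[:, 0] + 0.8 * z[:, 1]
    lo, hi = bootstrap_ci(x, y, n_boot=4000, seed=11)
    ref = sps.bootstrap(
        (x, y),
        spearman_statistic,
        n_resamples=4000,
        paired=True,
        vectorized=True,
        method="BCa",
        rng=np.random.default_rng(12),
    )
    assert lo == pytest.approx(ref.confidence_interval.low, abs=0.04)
    assert hi == pytest.approx(ref.confidence_interval.high, abs=0.04)


# ---------------------------------------------------------------------------
# rank tests


def test_mann_whitney_complete_separation():
    res = mann_whitney_u([1, 2, 3], [4, 5, 6])
    assert res.extra["U"] == 0.0  # U for the first group; 9 under the reversed convention
    assert res.coefficient < 0


def test_mann_whitney_null_rejection_rate():
    rng = np.random.default_rng(8)
    rejections = 0
    trials = 1000
    for _ in range(trials):
        a, b = rng.normal(size=(2, 20))
        if mann_whitney_u(a, b).p_two_tailed < 0.05:
            rejections += 1
    rate = rejections / trials
    assert 0.03 <= rate <= 0.07


def test_wilcoxon_identical_pairs_raise():
    with pytest.raises(ValueError, match="zero"):
        wilcoxon_signed_rank([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])


def test_wilcoxon_reports_standardised_z():
    rng = np.random.default_rng(9)
    a = rng.normal(size=30)
    b = a + rng.normal(0.8, 0.5, size=30)
    res = wilcoxon_signed_rank(a, b)
    assert res.coefficient < -1.96
    assert res.p_two_tailed < 0.05


# ---------------------------------------------------------------------------
# full pipeline


def test_planted_outlier_excluded_exactly_once():
    df = simulate_cohort(CohortSpec(n_subjects=12, plant_outlier=True, seed=0))
    rep = run_cohort_analysis(df, n_boot=100, seed=0)
    assert rep.excluded_ids == ["S001"]
    assert rep.n_initial == 12 and rep.n_analytic == 11


def test_too_few_subjects_after_exclusion_raises():
    df = simulate_cohort(CohortSpec(n_subjects=8, seed=1))
    df["memory_score"] = [20, 20, 21, 21, 20, 22, 19, 5]
    with pytest.raises(ValueError, match="after outlier exclusion"):
        run_cohort_analysis(df, n_boot=50, seed=1)


def test_missing_columns_raise():
    df = simulate_cohort(CohortSpec(seed=2)).drop(columns=["left_xi"])
    with pytest.raises(ValueError, match="missing"):
        run_cohort_analysis(df)


def test_null_cohort_type_i_error_near_nominal():
    """Left-xi partial correlation is 'significant' in about 5% of null runs."""
    hits = 0
    trials = 150
    for s in range(trials):
        df = simulate_cohort(
            CohortSpec(
                n_subjects=12,
                effect_xi_left=0.0,
                effect_age=0.0,
                noise_sd=1.0,
                seed=s,
            )
        )
        try:
            rep = run_cohort_analysis(df, n_boot=20, seed=s)
        except ValueError:
            continue
        if rep.partial_correlations.loc["left_xi", "p"] < 0.05:
            hits += 1
    rate = hits / trials
    # binomial 95% band around 0.05 at 150 trials, plus slack for the
    # data-dependent covariate selection
    assert 0.01 <= rate <= 0.10


def test_report_serialises_to_json():
    import json

    df = simulate_cohort(CohortSpec(n_subjects=12, plant_outlier=True, seed=3))
    rep = run_cohort_analysis(df, n_boot=50, seed=3)
    payload = json.dumps(rep.to_dict(), default=str)
    assert "partial_correlations" in payload
    assert rep.n_uncorrected_tests > 0
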
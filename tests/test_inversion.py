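import numpy as np
import pytest

import hippomre.inversion as inv_mod
from hippomre.fields import ComplexModulusField
from hippomre.forward import ForwardConfig, add_noise, solve_time_harmonic
from hippomre.inversion import (
    InversionConfig,
    _misfit_and_grad,
    invert,
    objective,
)
from hippomre.phantom import make_phantom, reference_phantom_spec
from hippomre.roi import RegionMaskSet


@pytest.fixture(scope="module")
def two_region():
    props, masks = make_phantom(
        reference_phantom_spec(grid_shape=(32, 32), voxel_size_mm=1.6)
    )
    exps = [ForwardConfig(drive_axis=0), ForwardConfig(drive_axis=1)]
    clean = [solve_time_harmonic(props, e) for e in exps]
    return props, masks, exps, clean


def test_objective_zero_at_truth_with_noiseless_data(two_region):
    props, masks, exps, clean = two_region
    cfg = InversionConfig(experiments=exps, spr_regions=["hippocampus"])
    # the inclusion is uniform, so the SPR penalty vanishes at the truth too
    assert objective(props, clean, masks, cfg) < 1e-18


def test_objective_alpha_zero_is_pure_misfit(two_region):
    props, masks, exps, clean = two_region
    perturbed = ComplexModulusField(props.gp * 1.2, props.gpp, props.spacing_mm)
    cfg0 = InversionConfig(experiments=exps, spr_weight=0.0, spr_regions=["hippocampus"])
    mis, _, _ = _misfit_and_grad(
        perturbed.gp, perturbed.gpp, perturbed.spacing_mm, clean, exps, want_grad=False
    )
    assert objective(perturbed, clean, masks, cfg0) == pytest.approx(mis)


def test_uniform_roi_has_zero_penalty_for_any_alpha(two_region):
    props, masks, exps, clean = two_region
    big = InversionConfig(experiments=exps, spr_weight=1e3, spr_regions=["hippocampus"])
    zero = InversionConfig(experiments=exps, spr_weight=0.0, spr_regions=["hippocampus"])
    # properties are uniform inside the ROI, so alpha is irrelevant
    assert objective(props, clean, masks, big) == pytest.approx(
        objective(props, clean, masks, zero)
    )


def test_empty_roi_raises(two_region):
    props, masks, exps, clean = two_region
    empty = RegionMaskSet(
        masks={"void": np.zeros(props.shape, dtype=np.uint8)},
        spacing_mm=props.spacing_mm,
    )
    cfg = InversionConfig(experiments=exps, spr_regions=["void"])
    with pytest.raises(ValueError, match="void"):
        objective(props, clean, masks=empty, cfg=cfg)


def test_adjoint_gradient_matches_finite_differences():
    rng = np.random.default_rng(0)
    shape = (10, 12)
    gp = 2000.0 + 200.0 * rng.random(shape)
    gpp = 500.0 + 100.0 * rng.random(shape)
    cfg = ForwardConfig()
    data = solve_time_harmonic(
        ComplexModulusField(gp * 1.1, gpp * 0.9, 1.6), cfg
    )
    j0, g_gp, g_gpp = _misfit_and_grad(gp, gpp, 1.6, [data], [cfg])
    eps = 1e-3
    for i, j in [(3, 4), (5, 7), (1, 1)]:
        for arr, grad in ((gp, g_gp), (gpp, g_gpp)):
            bumped_gp, bumped_gpp = gp.copy(), gpp.copy()
            (bumped_gp if arr is gp else bumped_gpp)[i, j] += eps
            j1, _, _ = _misfit_and_grad(
                bumped_gp, bumped_gpp, 1.6, [data], [cfg], want_grad=False
            )
            fd = (j1 - j0) / eps
            assert fd == pytest.approx(grad[i, j], rel=1e-4, abs=1e-18)


def test_homogeneous_truth_is_a_fixed_point(two_region):
    _, masks, exps, _ = two_region
    truth = ComplexModulusField(
        np.full((32, 32), 2500.0), np.full((32, 32), 800.0), 1.6
    )
    clean = [solve_time_harmonic(truth, e) for e in exps]
    cfg = InversionConfig(
        experiments=exps,
        spr_regions=["hippocampus"],
        init_gp_pa=2500.0,
        init_gpp_pa=800.0,
        max_global_iters=5,
    )
    res = invert(clean, masks, cfg)
    assert res.converged
    assert res.iterations <= 2
    np.testing.assert_allclose(res.estimate.gp, truth.gp, rtol=1e-8)
    np.testing.assert_allclose(res.estimate.gpp, truth.gpp, rtol=1e-6)


def test_matched_grid_recovery_and_monotone_objective(two_region):
    """ROI means recovered within 10% on matched-grid noisy data."""
    props, masks, exps, clean = two_region
    noisy = []
    for i, f in enumerate(clean):
        rms = float(np.sqrt(np.mean(np.abs(f.u) ** 2)))
        noisy.append(add_noise(f, 0.01 * rms, seed=50 + i))
    cfg = InversionConfig(
        experiments=exps, spr_regions=["hippocampus"], max_global_iters=25
    )
    res = invert(noisy, masks, cfg)
    hist = np.asarray(res.objective_history)
    assert np.all(np.diff(hist) <= 1e-12)
    roi = masks.masks["hippocampus"] > 0
    assert res.estimate.gp[roi].mean() == pytest.approx(2750.0, rel=0.10)
    assert res.estimate.gpp[roi].mean() == pytest.approx(990.0, rel=0.10)
    assert res.estimate.gp.min() >= cfg.gp_bounds_pa[0]
    assert res.estimate.gp.max() <= cfg.gp_bounds_pa[1]


def test_spr_limit_shrinks_roi_variance(two_region):
    """Within-ROI spread is non-increasing in the SPR weight."""
    props, masks, exps, clean = two_region
    noisy = []
    for i, f in enumerate(clean):
        rms = float(np.sqrt(np.mean(np.abs(f.u) ** 2)))
        noisy.append(add_noise(f, 0.02 * rms, seed=60 + i))
    roi = masks.masks["hippocampus"] > 0
    cvs = []
    for weight in (0.0, 1e-10, 1e-6):
        cfg = InversionConfig(
            experiments=exps,
            spr_regions=["hippocampus"],
            spr_weight=weight,
            max_global_iters=12,
        )
        est = invert(noisy, masks, cfg).estimate
        cvs.append(est.gp[roi].std() / est.gp[roi].mean())
    assert cvs[1] <= cvs[0] + 1e-9
    assert cvs[2] <= cvs[1] + 1e-9
    assert cvs[2] < 0.01  # strong-prior limit: ROI near-uniform


def test_mismatched_experiment_count_raises(two_region):
    _, masks, exps, clean = two_region
    cfg = InversionConfig(experiments=exps[:1], spr_regions=["hippocampus"])
    with pytest.raises(ValueError, match="ForwardConfig"):
        invert(clean, masks, cfg)
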
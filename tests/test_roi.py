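import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hippomre.fields import ComplexModulusField
from hippomre.roi import (
    RegionMaskSet,
    damping_ratio,
    derived_maps,
    exclude_csf,
    exclude_csf_in_set,
    regional_summary,
    shear_stiffness,
    transform_mask,
)


# ---------------------------------------------------------------------------
# mask transfer


def _box_mask(n=16, lo=4, hi=12):
    m = np.zeros((n, n))
    m[lo:hi, lo:hi] = 1
    return m


def test_identity_transform_preserves_mask():
    m = _box_mask()
    out = transform_mask(m, np.eye(3), m.shape)
    np.testing.assert_array_equal(out, m.astype(np.uint8))


@pytest.mark.parametrize("shift,included", [(0.06, False), (0.04, True)])
def test_threshold_at_95_percent_occupancy(shift, included):
    """Occupancy 0.94 is excluded, 0.96 is included."""
    m = _box_mask()
    affine = np.eye(3)
    affine[0, 2] = shift  # target voxel centre maps 'shift' into the source
    out = transform_mask(m, affine, m.shape)
    # trailing-edge row interpolates to 1 - shift
    assert bool(out[11, 8]) is included


def test_half_voxel_translation_matches_brute_force_interpolation():
    m = _box_mask()
    affine = np.eye(3)
    affine[:2, 2] = [0.5, 0.25]
    out = transform_mask(m, affine, m.shape)

    def interp(si, sj):
        i0, j0 = int(np.floor(si)), int(np.floor(sj))
        di, dj = si - i0, sj - j0
        val = 0.0
        for a in (0, 1):
            for b in (0, 1):
                ii, jj = i0 + a, j0 + b
                if 0 <= ii < m.shape[0] and 0 <= jj < m.shape[1]:
                    w = (di if a else 1 - di) * (dj if b else 1 - dj)
                    val += w * m[ii, jj]
        return val

    brute = np.zeros_like(m, dtype=np.uint8)
    for i in range(m.shape[0]):
        for j in range(m.shape[1]):
            brute[i, j] = interp(i + 0.5, j + 0.25) >= 0.95
    np.testing.assert_array_equal(out, brute)


def test_singular_affine_raises():
    with pytest.raises(ValueError, match="invertible"):
        transform_mask(_box_mask(), np.zeros((3, 3)), (16, 16))


# ---------------------------------------------------------------------------
# CSF exclusion


def test_exclude_csf_noop_without_csf():
    m = _box_mask()
    cleaned, removed = exclude_csf(m, np.zeros_like(m))
    np.testing.assert_array_equal(cleaned, m.astype(np.uint8))
    assert removed.sum() == 0


def test_any_csf_fraction_removes_voxel():
    m = _box_mask()
    pv = np.zeros_like(m)
    pv[5, 5] = 0.01
    cleaned, removed = exclude_csf(m, pv)
    assert cleaned[5, 5] == 0
    assert removed[5, 5] == 1
    assert cleaned.sum() == m.sum() - 1


def test_toy_count_by_hand():
    m = np.zeros((4, 4))
    m.ravel()[:10] = 1
    pv = np.zeros((4, 4))
    pv.ravel()[[1, 4, 7]] = 0.5
    cleaned, _ = exclude_csf(m, pv)
    assert cleaned.sum() == 7


def test_invalid_partial_volume_raises():
    m = _box_mask()
    with pytest.raises(ValueError):
        exclude_csf(m, np.full_like(m, 1.5))


def test_exclusion_never_adds_voxels_and_sets_provenance():
    pv = np.zeros((16, 16))
    pv[6:8, 6:8] = 0.3
    ms = RegionMaskSet(masks={"hc": _box_mask().astype(np.uint8)}, csf_pv=pv)
    exclude_csf_in_set(ms)
    assert ms.masks["hc"].sum() < _box_mask().sum()
    assert "csf_excluded" in ms.provenance["hc"]
    assert ms.csf_removed["hc"].sum() == 4


# ---------------------------------------------------------------------------
# derived maps


def test_damping_ratio_and_stiffness_formulas():
    assert damping_ratio(np.array(1000.0), np.array(350.0)) == pytest.approx(0.175)
    # elastic limit: mu reduces to G'
    assert damping_ratio(np.array(2500.0), np.array(0.0)) == 0.0
    assert shear_stiffness(np.array(2500.0), np.array(0.0)) == pytest.approx(2500.0)
    # worked arithmetic: |G*| = 2118.96 Pa, mu = 2180.2 Pa
    gabs = np.hypot(2000.0, 700.0)
    assert gabs == pytest.approx(2118.96, abs=0.01)
    assert shear_stiffness(np.array(2000.0), np.array(700.0)) == pytest.approx(
        2180.2, abs=0.1
    )


def test_nonpositive_storage_modulus_masked_with_warning():
    gp = np.array([[2000.0, -5.0], [1000.0, 0.0]])
    gpp = np.full((2, 2), 300.0)
    with pytest.warns(UserWarning, match="masked"):
        maps = derived_maps(ComplexModulusField(gp, gpp, 1.6))
    assert maps.valid.sum() == 2
    assert np.isnan(maps.xi[0, 1]) and np.isnan(maps.mu[1, 1])


@settings(deadline=None, derandomize=True, max_examples=50)
@given(
    st.floats(100.0, 10000.0),
    st.floats(0.0, 5000.0),
    st.floats(1.0, 100.0),
)
def test_stiffness_dominates_modulus_and_xi_monotone(gp, gpp, dg):
    """mu >= |G*| >= G' (equality iff G''=0); xi strictly increasing in G''."""
    gabs = np.hypot(gp, gpp)
    mu = float(shear_stiffness(np.array(gp), np.array(gpp)))
    assert mu >= gabs - 1e-9
    assert gabs >= gp
    if gpp == 0:
        assert mu == pytest.approx(gp)
    assert damping_ratio(np.array(gp), np.array(gpp + dg)) > damping_ratio(
        np.array(gp), np.array(gpp)
    )
    # xi = 0.5 iff G'' = G'
    assert damping_ratio(np.array(gp), np.array(gp)) == pytest.approx(0.5)


# ---------------------------------------------------------------------------
# regional summaries


def _uniform_setup():
    n = 16
    gp = np.full((n, n), 2750.0)
    gpp = np.full((n, n), 990.0)
    props = ComplexModulusField(gp, gpp, 1.6)
    mask = np.zeros((n, n), dtype=np.uint8)
    mask[4:10, 4:10] = 1
    ms = RegionMaskSet(masks={"hc": mask}, csf_pv=np.zeros((n, n)))
    exclude_csf_in_set(ms)
    return derived_maps(props), ms


def test_uniform_region_mean_is_exact():
    maps, ms = _uniform_setup()
    summ = regional_summary(maps, ms)["hc"]
    assert summ.mean_xi == pytest.approx(0.18)
    assert summ.median_xi == pytest.approx(0.18)


def test_volume_and_etiv_normalisation():
    n = 12
    props = ComplexModulusField(
        np.full((n, n, n), 2500.0), np.full((n, n, n), 500.0), 1.6
    )
    mask = np.zeros((n, n, n), dtype=np.uint8)
    mask[1:11, 1:11, 1:11] = 1  # exactly 1000 voxels
    ms = RegionMaskSet(masks={"hc": mask}, csf_pv=np.zeros((n, n, n)))
    exclude_csf_in_set(ms)
    summ = regional_summary(derived_maps(props), ms, etiv_cm3=1450.0)["hc"]
    assert summ.volume_cm3 == pytest.approx(4.096)
    assert 3.17 <= summ.volume_cm3 <= 5.16  # plausible unilateral HC volume
    assert summ.normalized_volume == pytest.approx(4.096 / 1450.0)


def test_bilateral_equals_weighted_mean_of_unilateral():
    n = 20
    gp = np.full((n, n), 2000.0)
    gpp = np.full((n, n), 400.0)
    gp[2:6, 2:8] = 2750.0   # left: 24 voxels
    gpp[2:6, 2:8] = 990.0
    gp[12:18, 12:16] = 3100.0  # right: 24 voxels, different values
    gpp[12:18, 12:16] = 800.0
    left = np.zeros((n, n), dtype=np.uint8)
    left[2:6, 2:8] = 1
    right = np.zeros((n, n), dtype=np.uint8)
    right[12:18, 12:16] = 1
    ms = RegionMaskSet(
        masks={"left_hc": left, "right_hc": right}, csf_pv=np.zeros((n, n))
    ).with_bilateral()
    exclude_csf_in_set(ms)
    out = regional_summary(derived_maps(ComplexModulusField(gp, gpp, 1.6)), ms)
    nl, nr = out["left_hc"].voxel_count, out["right_hc"].voxel_count
    expected = (
        nl * out["left_hc"].mean_xi + nr * out["right_hc"].mean_xi
    ) / (nl + nr)
    assert out["bilateral_hc"].mean_xi == pytest.approx(expected)


def test_summary_requires_csf_excluded_masks():
    maps, _ = _uniform_setup()
    raw = RegionMaskSet(
        masks={"hc": _box_mask().astype(np.uint8)}, csf_pv=np.zeros((16, 16))
    )
    with pytest.raises(ValueError, match="CSF"):
        regional_summary(maps, raw)


def test_empty_region_after_exclusion_raises():
    maps, _ = _uniform_setup()
    mask = np.zeros((16, 16), dtype=np.uint8)
    mask[5, 5] = 1
    pv = np.zeros((16, 16))
    pv[5, 5] = 1.0
    ms = RegionMaskSet(masks={"gone": mask}, csf_pv=pv)
    exclude_csf_in_set(ms)
    with pytest.raises(ValueError, match="gone"):
        regional_summary(maps, ms)
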
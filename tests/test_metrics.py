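"""Background noise, CNR/Rose visibility, recovery coefficients, SUV metrics."""

import numpy as np
import pytest

import petphantomqa as qa
from petphantomqa.metrics import background_metrics, sphere_metrics, suv_peak


def _three_vois(shape=(4, 4, 6)):
    """Three disjoint 2-voxel VOIs in a small volume."""
    vois = []
    for k in range(3):
        m = np.zeros(shape, dtype=bool)
        m[k, 0, 0] = m[k, 0, 1] = True
        vois.append(m)
    return vois


def test_cov_bg_constant_image_is_zero():
    img = np.full((4, 4, 6), 7.0)
    assert qa.cov_bg(img, _three_vois()) == 0.0


def test_cov_bg_hand_computed_two_point_vois():
    """VOI values {90, 110}: sample SD = 10*sqrt(2), mean 100 -> 14.14%."""
    img = np.zeros((4, 4, 6))
    vois = _three_vois()
    for m in vois:
        img[m] = [90.0, 110.0]
    expected = 100.0 * 10.0 * np.sqrt(2.0) / 100.0
    assert qa.cov_bg(img, vois) == pytest.approx(expected, abs=1e-12)


def test_cov_bg_poisson_surrogate(coarse_labels, background_vois):
    """lambda = 64 counts/voxel -> CoV ~ 12.5% over the 131 ml VOIs."""
    lam = 64.0
    rng = np.random.default_rng(12)
    img = rng.poisson(lam, size=coarse_labels.labels.shape).astype(float)
    cov = qa.cov_bg(img, background_vois)
    n = background_vois[0].sum()
    se = (100.0 / np.sqrt(lam)) / np.sqrt(2 * n)
    assert abs(cov - 12.5) < 3 * se + 0.1


def test_cov_bg_rejects_nonpositive_mean():
    img = np.zeros((4, 4, 6))
    with pytest.raises(ValueError, match="non-positive"):
        qa.cov_bg(img, _three_vois())


def test_cnr_formula_arithmetic():
    """sphere mean 21.2, bg mean 5.3, mean SD 1.59 -> CNR = 10.0."""
    img = np.zeros((6, 4, 6))
    vois = []
    for k in range(3):
        m = np.zeros_like(img, dtype=bool)
        m[k, 0, 0] = m[k, 0, 1] = True
        vois.append(m)
        # mean 5.3, sample SD 1.59 from two points: 5.3 +/- 1.59/sqrt(2)
        h = 1.59 / np.sqrt(2.0)
        img[m] = [5.3 - h, 5.3 + h]
    sphere = np.zeros_like(img, dtype=bool)
    sphere[5, 2, 2] = True
    img[sphere] = 21.2
    assert qa.cnr(img, sphere, vois) == pytest.approx(10.0, rel=1e-12)


def test_cnr_null_contrast_is_zero():
    img = np.zeros((6, 4, 6))
    vois = _three_vois((6, 4, 6))
    for m in vois:
        img[m] = [5.0, 7.0]
    sphere = np.zeros_like(img, dtype=bool)
    sphere[5, 3, 3] = sphere[5, 3, 4] = True
    img[sphere] = 6.0  # equals background mean
    assert qa.cnr(img, sphere, vois) == pytest.approx(0.0, abs=1e-12)


def test_cnr_affine_invariance(reference_scan, voi_set):
    m = voi_set.sphere_vois[22.0]
    base = qa.cnr(reference_scan.values, m, voi_set.background_vois)
    scaled = qa.cnr(2.5 * reference_scan.values + 1.0, m, voi_set.background_vois)
    assert scaled == pytest.approx(base, rel=1e-10)


def test_cnr_noiseless_image_reports_infinite():
    img = np.zeros((6, 4, 6))
    vois = _three_vois((6, 4, 6))
    for m in vois:
        img[m] = 5.3
    sphere = np.zeros_like(img, dtype=bool)
    sphere[5, 3, 3] = True
    img[sphere] = 21.2
    assert qa.cnr(img, sphere, vois) == float("inf")


@pytest.mark.parametrize("value, visible", [(5.0, True), (3.45, False), (10.0, True)])
def test_rose_criterion_boundary(value, visible):
    assert qa.is_visible(value) is visible


def test_recovery_noiseless_unblurred_is_unity(coarse_labels):
    setup = qa.AcquisitionSetup(sbr=4.0)
    act = qa.activity_map(coarse_labels, setup)
    for d in coarse_labels.sphere_diameters_mm:
        rc_mean, rc_max = qa.recovery_coefficients(
            act, coarse_labels.sphere_mask(d), 21.2
        )
        assert rc_mean == pytest.approx(1.0, abs=1e-12)
        assert rc_max == pytest.approx(1.0, abs=1e-12)


def test_recovery_ratio_invariance(reference_scan, voi_set):
    m = voi_set.sphere_vois[17.0]
    a = qa.recovery_coefficients(reference_scan.values, m, 21.2)
    b = qa.recovery_coefficients(2.0 * reference_scan.values, m, 42.4)
    assert a == pytest.approx(b, rel=1e-12)


def test_partial_volume_rc_monotone_in_diameter(coarse_labels):
    """Under heavy PSF blur, RC_mean grows with sphere size (noiseless)."""
    setup = qa.AcquisitionSetup(sbr=4.0)
    act = qa.activity_map(coarse_labels, setup)
    scan = qa.simulate(
        act, setup, 60.0, coarse_labels.grid, psf_fwhm_mm=10.0, mode="expectation"
    )
    rcs = [
        qa.recovery_coefficients(scan.values, coarse_labels.sphere_mask(d), 21.2)[0]
        for d in coarse_labels.sphere_diameters_mm
    ]
    assert rcs == sorted(rcs)
    assert rcs[0] < rcs[-1]


def test_recovery_rejects_bad_inputs(coarse_labels):
    with pytest.raises(ValueError):
        qa.recovery_coefficients(np.ones(coarse_labels.labels.shape),
                                 coarse_labels.sphere_mask(10.0), 0.0)


def test_suv_peak_constant_image(coarse_labels):
    img = np.full(coarse_labels.labels.shape, 4.2)
    m = coarse_labels.sphere_mask(37.0)
    assert suv_peak(img, m, coarse_labels.grid) == pytest.approx(4.2)


def test_suv_peak_below_max_for_isolated_hot_voxel(coarse_labels):
    img = np.zeros(coarse_labels.labels.shape)
    m = coarse_labels.sphere_mask(37.0)
    hot = tuple(np.argwhere(m)[len(np.argwhere(m)) // 2])
    img[hot] = 100.0
    peak = suv_peak(img, m, coarse_labels.grid)
    assert 0.0 < peak < 100.0


def test_suv_peak_plateau_on_noiseless_large_sphere(coarse_labels):
    setup = qa.AcquisitionSetup(sbr=4.0)
    act = qa.activity_map(coarse_labels, setup)
    m = coarse_labels.sphere_mask(37.0)
    peak = suv_peak(act, m, coarse_labels.grid)
    assert peak == pytest.approx(21.2, rel=0.01)


def test_suv_peak_small_mask_falls_back_with_warning(coarse_labels):
    img = np.full(coarse_labels.labels.shape, 3.0)
    m = np.zeros_like(img, dtype=bool)
    m[5, 5, 5] = True
    with pytest.warns(UserWarning, match="mask mean"):
        val = suv_peak(img, m, coarse_labels.grid)
    assert val == 3.0


def test_delta_suv_identity_and_shift(reference_scan, voi_set):
    ref = reference_scan.values
    d0 = qa.delta_suv(ref, ref, voi_set.sphere_vois)
    assert d0["mean_dmean"] == 0.0 and d0["sd_dmean"] == 0.0
    assert d0["mean_dmax"] == 0.0 and d0["sd_dmax"] == 0.0
    shifted = qa.delta_suv(ref + 0.7, ref, voi_set.sphere_vois)
    for dmean, dmax in shifted["per_sphere"].values():
        assert dmean == pytest.approx(0.7, abs=1e-9)
        assert dmax == pytest.approx(0.7, abs=1e-9)
    assert shifted["sd_dmean"] == pytest.approx(0.0, abs=1e-9)


def test_delta_suv_matches_brute_force(coarse_labels, calibrated_setup, coarse_activity, voi_set, reference_scan):
    other = qa.simulate(
        coarse_activity, calibrated_setup, 40.0, coarse_labels.grid, 4.0, seed=77
    )
    out = qa.delta_suv(other.values, reference_scan.values, voi_set.sphere_vois)
    for d, m in voi_set.sphere_vois.items():
        dmean = abs(other.values[m].mean() - reference_scan.values[m].mean())
        dmax = abs(other.values[m].max() - reference_scan.values[m].max())
        assert out["per_sphere"][d] == pytest.approx((dmean, dmax), rel=1e-12)


def test_delta_suv_grid_mismatch_raises(reference_scan, voi_set):
    with pytest.raises(ValueError, match="grid"):
        qa.delta_suv(np.zeros((3, 3, 3)), reference_scan.values, voi_set.sphere_vois)


def test_sphere_metrics_orders_suv_statistics(reference_scan, voi_set):
    sm = sphere_metrics(reference_scan.values, voi_set, 21.2, 37.0)
    assert sm.suv_max >= sm.suv_peak >= sm.suv_mean
    assert sm.visible == (sm.cnr >= 5.0)
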
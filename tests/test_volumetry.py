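"""Volumetry, rater emulation, Bland–Altman agreement and SNR/CNR."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from renal_mpmri.geometry import AcquisitionGeometry
from renal_mpmri.phantom import LesionSpec, PhantomSpec, make_phantom
from renal_mpmri.simulate import simulate_t2w
from renal_mpmri.tissue import TISSUE_CLASSES
from renal_mpmri.volumetry import (
    LesionROI,
    bland_altman,
    correlate_parameters,
    digitize_lesion,
    match_lesions,
    roi_volume,
    snr_cnr,
)


def lesion(lesion_id, center, radii):
    return LesionSpec(lesion_id, center, radii, "cystic",
                      TISSUE_CLASSES["cystic"])


def study_geometry(thickness, n_slices):
    return AcquisitionGeometry((30.0, 30.0), (256, 256), thickness, n_slices)


class TestRoiVolume:
    def test_single_voxel_at_study_resolution(self):
        geom = study_geometry(0.5, 32)
        mask = np.zeros(geom.shape, bool)
        mask[10, 10, 5] = True
        roi = LesionROI(1, mask, geom)
        assert roi_volume(roi) == pytest.approx((30 / 256) ** 2 * 0.5, rel=1e-12)
        assert roi_volume(roi) == pytest.approx(0.006866, abs=5e-7)

    def test_linear_in_slice_thickness(self):
        mask = np.zeros((256, 256, 16), bool)
        mask[10:14, 10:14, 5] = True
        v_thin = roi_volume(LesionROI(1, mask[:, :, :32].copy(), study_geometry(0.5, 16)))
        v_thick = roi_volume(LesionROI(1, mask, study_geometry(1.0, 16)))
        assert v_thick == pytest.approx(2.0 * v_thin, rel=1e-12)

    def test_additive_over_disjoint_rois(self):
        geom = study_geometry(1.0, 16)
        a = np.zeros(geom.shape, bool)
        b = np.zeros(geom.shape, bool)
        a[5:9, 5:9, 3] = True
        b[100:104, 100:110, 8] = True
        va = roi_volume(LesionROI(1, a, geom))
        vb = roi_volume(LesionROI(2, b, geom))
        vab = roi_volume(LesionROI(3, a | b, geom))
        assert vab == pytest.approx(va + vb, rel=1e-12)

    def test_empty_roi_warns_and_returns_zero(self):
        geom = study_geometry(1.0, 4)
        with pytest.warns(UserWarning, match="empty ROI"):
            v = roi_volume(LesionROI(1, np.zeros(geom.shape, bool), geom))
        assert v == 0.0


class TestDigitizeLesion:
    def test_voxel_sized_lesion_maps_to_single_voxel(self):
        geom = AcquisitionGeometry((8.0, 8.0), (8, 8), 1.0, 4)
        # ellipsoid inscribed in the voxel centred at (2.5, 3.5, 1.5)
        les = lesion(1, (2.5, 3.5, 1.5), (0.5, 0.5, 0.5))
        roi = digitize_lesion(les, geom, fraction_threshold=0.5)
        assert roi.n_voxels == 1
        assert roi.mask[2, 3, 1]

    def test_small_sphere_mid_slab_overestimated_by_thickness(self):
        # d = 0.4 mm sphere centred mid-slab of a 1 mm slice: the rater sees
        # its equatorial disc on one slice and the full slice thickness is
        # attributed to it
        geom = study_geometry(1.0, 16)
        les = lesion(1, (15.0, 15.0, 8.5), (0.2, 0.2, 0.2))
        roi = digitize_lesion(les, geom)
        assert len(roi.slice_indices) == 1
        assert roi_volume(roi) >= les.volume_mm3

    def test_unit_sphere_volume_within_15pct_at_half_mm_slices(self):
        geom = study_geometry(0.5, 32)
        les = lesion(1, (15.03, 14.96, 8.02), (0.62, 0.62, 0.62))
        roi = digitize_lesion(les, geom)
        assert roi_volume(roi) == pytest.approx(les.volume_mm3, rel=0.15)

    def test_lesion_outside_fov_yields_empty_roi_with_warning(self):
        geom = study_geometry(1.0, 8)
        les = lesion(1, (60.0, 60.0, 60.0), (0.5, 0.5, 0.5))
        with pytest.warns(UserWarning, match="not captured"):
            roi = digitize_lesion(les, geom)
        assert roi.n_voxels == 0

    def test_digitized_volume_converges_with_resolution(self):
        # mean |error| over random sub-voxel offsets falls as in-plane and
        # slice resolution double twice
        offsets = np.random.default_rng(3).uniform(-0.5, 0.5, (8, 3))
        mean_errs = []
        for m, th, ns in ((64, 1.0, 4), (128, 0.5, 8), (256, 0.25, 16)):
            geom = AcquisitionGeometry((8.0, 8.0), (m, m), th, ns)
            errs = []
            for o in offsets:
                les = lesion(1, (4 + o[0], 4 + o[1], 2 + o[2]),
                             (0.62, 0.62, 0.62))
                v = roi_volume(digitize_lesion(les, geom))
                errs.append(abs(v - les.volume_mm3) / les.volume_mm3)
            mean_errs.append(np.mean(errs))
        assert mean_errs[0] > mean_errs[1] > mean_errs[2]
        assert mean_errs[2] < 0.05

    def test_thick_slices_overestimate_small_lesions_more(self):
        # the 1 mm vs 0.5 mm volume ratio is larger for lesions ≤ 0.25 mm³
        # than for lesions > 1 mm³
        rng = np.random.default_rng(42)
        g1 = study_geometry(1.0, 16)
        g05 = study_geometry(0.5, 32)
        small, large = [], []
        for i in range(60):
            vol = float(np.exp(rng.uniform(np.log(0.016), np.log(5.12))))
            r = (3 * vol / (4 * np.pi)) ** (1 / 3)
            c = (15 + rng.uniform(-3, 3), 15 + rng.uniform(-3, 3),
                 8 + rng.uniform(-2, 2))
            les = lesion(i + 1, c, (r, r, r))
            v1 = roi_volume(digitize_lesion(les, g1))
            v05 = roi_volume(digitize_lesion(les, g05))
            if v1 > 0 and v05 > 0:
                if vol <= 0.25:
                    small.append(v1 / v05)
                elif vol > 1.0:
                    large.append(v1 / v05)
        assert len(small) >= 5 and len(large) >= 5
        assert np.mean(small) > np.mean(large)


class TestBlandAltman:
    def test_identical_lists(self):
        res = bland_altman([(1.0, 1.0), (2.0, 2.0), (3.0, 3.0)])
        assert res.bias == 0.0
        assert res.loa_low == res.loa_high == 0.0
        assert res.pearson_r is not None  # both vary → defined, and r = 1
        assert res.pearson_r == pytest.approx(1.0)

    def test_constant_list_has_undefined_correlation(self):
        res = bland_altman([(1.0, 1.0), (1.0, 1.0), (1.0, 1.0)])
        assert res.bias == 0.0
        assert res.pearson_r is None and res.pearson_p is None

    def test_alternating_differences_hand_computation(self):
        pairs = [(1.0, 0.0), (0.0, 1.0), (1.0, 0.0), (0.0, 1.0)]
        res = bland_altman(pairs)
        assert res.bias == 0.0
        assert res.sd_diff == pytest.approx(1.1547, abs=1e-4)
        assert res.loa_high == pytest.approx(2.2632, abs=1e-3)
        assert res.loa_low == pytest.approx(-2.2632, abs=1e-3)

    def test_proportional_readings(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = bland_altman(np.stack([a, 2 * a], axis=1))
        assert res.pearson_r == pytest.approx(1.0)
        assert res.bias == pytest.approx(-a.mean())

    @given(st.integers(0, 10_000))
    @settings(max_examples=100, deadline=None)
    def test_equals_first_principles_recomputation(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 40))
        a = rng.normal(1.0, 0.5, n)
        b = a + rng.normal(0.1, 0.3, n)
        res = bland_altman(np.stack([a, b], axis=1))
        d = a - b
        sd = np.sqrt(np.sum((d - d.mean()) ** 2) / (n - 1))
        assert res.bias == pytest.approx(d.mean(), rel=1e-12, abs=1e-12)
        assert res.loa_low == pytest.approx(d.mean() - 1.96 * sd, rel=1e-9,
                                            abs=1e-12)
        assert res.loa_high == pytest.approx(d.mean() + 1.96 * sd, rel=1e-9,
                                             abs=1e-12)
        if res.pearson_r is not None:
            r_ref, p_ref = stats.pearsonr(a, b)
            assert res.pearson_r == pytest.approx(r_ref, rel=1e-9)
            assert res.pearson_p == pytest.approx(p_ref, rel=1e-6)


class TestSnrCnr:
    def rois(self, shape):
        sig = np.zeros(shape, bool)
        ref = np.zeros(shape, bool)
        noi = np.zeros(shape, bool)
        sig[:2], ref[2:4], noi[4:] = True, True, True
        return sig, ref, noi

    def test_textbook_values(self, rng):
        shape = (6, 50, 1)
        img = np.zeros(shape)
        sig, ref, noi = self.rois(shape)
        img[sig], img[ref] = 100.0, 60.0
        img[noi] = rng.normal(0.0, 5.0, img[noi].shape)
        noise_sd = img[noi].std(ddof=1)
        snr, cnr = snr_cnr(img, sig, ref, noi)
        assert snr == pytest.approx(100.0 / noise_sd)
        assert cnr == pytest.approx(40.0 / noise_sd)

    def test_zero_noise_sd_is_an_error(self):
        shape = (6, 4, 1)
        img = np.ones(shape)
        sig, ref, noi = self.rois(shape)
        with pytest.raises(ValueError, match="zero standard deviation"):
            snr_cnr(img, sig, ref, noi)

    def test_2d_vs_3d_snr_ratio_follows_signal_model(self):
        # equal noise, different TR saturation: measured SNR ratio must track
        # the forward-model signal ratio
        geom = AcquisitionGeometry((8.0, 8.0), (64, 64), 1.0, 4)
        ph = make_phantom(PhantomSpec(kidneys=(), vessel=None, lesions=()), geom)
        ph.maps["pd"][:] = 1.0
        ph.maps["t1"][:] = 2.0
        ph.maps["t2"][:] = 40.0
        clean_2d = simulate_t2w(ph, 10.0, tr_s=3.0)
        clean_3d = simulate_t2w(ph, 9.0, tr_s=0.2)
        sigma = 0.01
        img_2d = simulate_t2w(ph, 10.0, tr_s=3.0, noise_sigma=sigma, seed=1)
        img_3d = simulate_t2w(ph, 9.0, tr_s=0.2, noise_sigma=sigma, seed=2)
        sig = np.zeros(geom.shape, bool)
        noi = np.zeros(geom.shape, bool)
        sig[10:40, 10:40, :] = True
        noi[45:, 45:, :] = True
        snr2, _ = snr_cnr(img_2d, sig, sig, noi)
        snr3, _ = snr_cnr(img_3d, sig, sig, noi)
        expected = clean_2d.mean() / clean_3d.mean()
        assert snr2 / snr3 == pytest.approx(expected, rel=0.05)


class TestCorrelateParameters:
    def test_perfect_correlation(self):
        import pandas as pd

        t = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [1.0, 2.0, 3.0, 4.0]})
        r, p, n = correlate_parameters(t, "x", "y")
        assert r == pytest.approx(1.0)
        assert p < 1e-6 and n == 4

    def test_orthogonal_pairs_uncorrelated(self):
        import pandas as pd

        t = pd.DataFrame({"x": [-1.0, 0.0, 1.0], "y": [1.0, -2.0, 1.0]})
        r, _, _ = correlate_parameters(t, "x", "y")
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_missing_rows_dropped_and_counted(self):
        import pandas as pd

        t = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0, 5.0],
                          "y": [1.1, np.nan, 3.0, 4.2, 5.1]})
        r, p, n = correlate_parameters(t, "x", "y")
        assert n == 3 and r is not None

    def test_too_few_pairs_is_no_value(self):
        import pandas as pd

        t = pd.DataFrame({"x": [1.0, np.nan], "y": [2.0, 1.0]})
        assert correlate_parameters(t, "x", "y") == (None, None, 1)

    def test_phantom_volume_ktrans_anticorrelation(self):
        # larger lesions are predominantly cystic (low K^trans) → negative r
        spec = PhantomSpec(seed=21, n_lesions_mean=60.0)
        geom = AcquisitionGeometry((30.0, 30.0), (64, 64), 1.0, 16)
        ph = make_phantom(spec, geom)
        r, p, n = correlate_parameters(ph.table, "volume_mm3", "ktrans_per_min")
        assert n >= 30
        assert r < 0


def test_match_lesions_by_world_overlap():
    g1 = AcquisitionGeometry((8.0, 8.0), (32, 32), 1.0, 8)
    g05 = AcquisitionGeometry((8.0, 8.0), (32, 32), 0.5, 16)
    specs = [lesion(i + 1, c, (0.7, 0.7, 0.7)) for i, c in
             enumerate([(2.0, 2.0, 4.0), (6.0, 6.0, 4.0), (2.0, 6.0, 4.0)])]
    rois_a = [digitize_lesion(s, g1) for s in specs]
    # reversed ids in the second reading
    rois_b = [
        LesionROI(10 - s.lesion_id, digitize_lesion(s, g05).mask, g05)
        for s in specs
    ]
    matches = match_lesions(rois_a, rois_b)
    assert matches == [(1, 9), (2, 8), (3, 7)]
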
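"""Phantom generator: rasterization accuracy, statistics and reproducibility."""

import numpy as np
import pytest

from renal_mpmri.geometry import AcquisitionGeometry
from renal_mpmri.phantom import (
    Ellipsoid,
    LesionSpec,
    PhantomSpec,
    ellipsoid_fraction,
    make_phantom,
    sample_lesions,
)
from renal_mpmri.tissue import TISSUE_CLASSES


def study_geometry(thickness=0.5, n_slices=32):
    return AcquisitionGeometry((30.0, 30.0), (256, 256), thickness, n_slices)


def test_empty_lesion_list_gives_uniform_background_maps(small_geometry):
    spec = PhantomSpec(kidneys=(), vessel=None, lesions=())
    ph = make_phantom(spec, small_geometry)
    bg = spec.tissues["background"]
    assert np.all(ph.maps["pd"] == bg.pd)
    assert np.all(ph.maps["t1"] == bg.t1_s)
    assert np.all(ph.maps["adc"] == bg.adc_mm2_s)
    assert ph.table.empty
    assert ph.lesion_fraction.max() == 0.0


def test_sphere_voxel_fraction_volume_matches_analytic():
    # r = 0.62 mm sphere: (4/3)π(0.62)³ ≈ 0.998 mm³
    geom = study_geometry()
    sphere = Ellipsoid((15.05, 14.97, 8.03), (0.62, 0.62, 0.62))
    box, frac = ellipsoid_fraction(sphere, geom)
    est = frac.sum() * geom.voxel_volume_mm3
    assert sphere.volume_mm3 == pytest.approx(0.998, abs=5e-4)
    assert est == pytest.approx(sphere.volume_mm3, rel=0.02)


@pytest.mark.parametrize("volume_mm3", [0.016, 0.25, 5.12])
def test_voxel_fraction_volume_within_2pct_across_study_size_range(volume_mm3):
    geom = study_geometry()
    r = (3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    rng = np.random.default_rng(1)
    for _ in range(3):
        c = (15 + rng.uniform(-0.4, 0.4), 15 + rng.uniform(-0.4, 0.4),
             8 + rng.uniform(-0.4, 0.4))
        sphere = Ellipsoid(c, (r, r, r))
        _, frac = ellipsoid_fraction(sphere, geom)
        est = frac.sum() * geom.voxel_volume_mm3
        assert est == pytest.approx(sphere.volume_mm3, rel=0.02)


def test_default_spec_draws_study_scale_lesion_population():
    spec = PhantomSpec(seed=7)
    lesions = sample_lesions(spec, np.random.default_rng(spec.seed))
    # count ~ Normal(36, 5.7): seed 7 draw must be plausible and ≥1
    assert 15 <= len(lesions) <= 60
    vols = np.array([l.volume_mm3 for l in lesions])
    assert vols.min() >= 0.016 and vols.max() <= 5.12
    assert {l.tissue_class for l in lesions} <= {"cystic", "papillary", "solid"}


def test_generation_is_reproducible_for_fixed_seed():
    spec = PhantomSpec(seed=11)
    geom = AcquisitionGeometry((30.0, 30.0), (64, 64), 1.0, 16)
    a = make_phantom(spec, geom)
    b = make_phantom(spec, geom)
    for name in a.maps:
        np.testing.assert_array_equal(a.maps[name], b.maps[name])
    assert a.table.equals(b.table)


def test_tissue_fractions_conserve_to_unity():
    spec = PhantomSpec(seed=3)
    geom = AcquisitionGeometry((30.0, 30.0), (64, 64), 1.0, 16)
    ph = make_phantom(spec, geom)
    total = ph.lesion_fraction + ph.kidney_fraction + ph.vessel_fraction
    assert total.max() <= 1.0 + 1e-12


def test_pure_lesion_voxels_carry_lesion_parameters(small_geometry):
    les = LesionSpec(1, (4.5, 4.5, 1.5), (1.5, 1.5, 1.5), "papillary",
                     TISSUE_CLASSES["papillary"])
    spec = PhantomSpec(kidneys=(), vessel=None, lesions=(les,))
    ph = make_phantom(spec, small_geometry)
    pure = ph.lesion_fraction > 0.999
    assert pure.any()
    np.testing.assert_allclose(ph.maps["adc"][pure], les.params.adc_mm2_s,
                               rtol=1e-3)
    np.testing.assert_allclose(ph.maps["t1"][pure], les.params.t1_s, rtol=1e-3)


def test_lesion_outside_fov_warns_and_is_clipped(small_geometry):
    lesion = LesionSpec(1, (50.0, 50.0, 50.0), (0.5, 0.5, 0.5), "cystic",
                        TISSUE_CLASSES["cystic"])
    spec = PhantomSpec(kidneys=(), vessel=None, lesions=(lesion,))
    with pytest.warns(UserWarning, match="outside the field of view"):
        ph = make_phantom(spec, small_geometry)
    assert ph.lesion_fraction.max() == 0.0
    assert ph.table.loc[0, "voxel_volume_mm3"] == 0.0


def test_overlapping_lesions_resolved_by_lesion_id_priority(small_geometry):
    a = LesionSpec(1, (4.5, 4.5, 1.5), (1.5, 1.5, 1.5), "cystic",
                   TISSUE_CLASSES["cystic"])
    b = LesionSpec(2, (4.5, 4.5, 1.5), (1.5, 1.5, 1.5), "solid",
                   TISSUE_CLASSES["solid"])
    spec = PhantomSpec(kidneys=(), vessel=None, lesions=(a, b))
    ph = make_phantom(spec, small_geometry)
    # the lower lesion_id claims its full voxel volume; the later lesion only
    # picks up boundary remainders, and every shared interior voxel carries
    # lesion 1's identity and parameters
    assert ph.table.loc[0, "voxel_volume_mm3"] == pytest.approx(
        a.volume_mm3, rel=0.02
    )
    assert ph.table.loc[1, "voxel_volume_mm3"] < ph.table.loc[0, "voxel_volume_mm3"]
    box, frac = ellipsoid_fraction(a.shape, small_geometry)
    core = np.zeros(small_geometry.shape, dtype=bool)
    core[box] = frac > 0.999  # voxels wholly inside lesion 1
    assert core.any() and np.all(ph.label[core] == 1)
    np.testing.assert_allclose(ph.maps["adc"][core], a.params.adc_mm2_s,
                               rtol=1e-3)
    # deterministic: a rebuild reproduces the same resolution
    ph2 = make_phantom(spec, small_geometry)
    np.testing.assert_array_equal(ph.label, ph2.label)


def test_invalid_specs_rejected():
    with pytest.raises(ValueError):
        PhantomSpec(volume_range_mm3=(0.0, 5.0))
    with pytest.raises(ValueError):
        Ellipsoid((0, 0, 0), (1.0, -1.0, 1.0))
    with pytest.raises(ValueError):
        LesionSpec(1, (0, 0, 0), (1, 1, 1), "adenocarcinoma",
                   TISSUE_CLASSES["solid"])
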
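#!/usr/bin/env python
"""Slice orientation and thickness effects on lesion volumetry.

Digitizes the same ground-truth lesions on axial-vs-coronal 1 mm stacks and
on 1 mm-vs-0.5 mm axial stacks, then quantifies agreement (Pearson r,
Bland–Altman bias and limits) and the small-lesion partial-volume
overestimation, and compares SNR between the 2D (TR 3 s) and 3D (TR 0.2 s)
T2-weighted regimes at matched noise.

Run from the repository root:  python analysis/02_optimal_detection.py
"""

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from renal_mpmri.geometry import AcquisitionGeometry
from renal_mpmri.phantom import PhantomSpec, make_phantom
from renal_mpmri.simulate import simulate_t2w
from renal_mpmri.volumetry import bland_altman, digitize_lesion, roi_volume, snr_cnr

SEED = 7
RESULTS = Path("results")


def volumes_on(lesions, geometry):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return {
            l.lesion_id: roi_volume(digitize_lesion(l, geometry))
            for l in lesions
        }


def describe(res, label):
    print(f"{label}: r = {res.pearson_r:.2f} (p = {res.pearson_p:.2g}), "
          f"bias = {res.bias:.3f} mm3, "
          f"LoA [{res.loa_low:.3f}, {res.loa_high:.3f}], n = {res.n_pairs}")


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    spec = PhantomSpec(seed=SEED)
    fine = AcquisitionGeometry((30.0, 30.0), (256, 256), 1.0, 16)
    phantom = make_phantom(spec, fine)
    lesions = phantom.lesions

    geoms = {
        "axial_1mm": AcquisitionGeometry((30, 30), (256, 256), 1.0, 16, "axial"),
        "coronal_1mm": AcquisitionGeometry((30, 30), (256, 256), 1.0, 30,
                                           "coronal"),
        "axial_0p5mm": AcquisitionGeometry((30, 30), (256, 256), 0.5, 32,
                                           "axial"),
    }
    vols = {k: volumes_on(lesions, g) for k, g in geoms.items()}
    table = pd.DataFrame({
        "lesion_id": [l.lesion_id for l in lesions],
        "true_volume_mm3": [l.volume_mm3 for l in lesions],
        **{k: [v[l.lesion_id] for l in lesions] for k, v in vols.items()},
    })
    table.to_csv(RESULTS / "detection_volumes.csv", index=False)

    # axial vs coronal, lesions detected in both
    both = table[(table.axial_1mm > 0) & (table.coronal_1mm > 0)]
    res_ac = bland_altman(both[["axial_1mm", "coronal_1mm"]].to_numpy())
    describe(res_ac, "axial vs coronal (1 mm)")

    # 1 mm vs 0.5 mm, lesions detected in both
    both2 = table[(table.axial_1mm > 0) & (table.axial_0p5mm > 0)]
    res_th = bland_altman(both2[["axial_1mm", "axial_0p5mm"]].to_numpy())
    describe(res_th, "1 mm vs 0.5 mm (axial)")
    small = both2[both2.true_volume_mm3 <= 0.25]
    large = both2[both2.true_volume_mm3 > 1.0]
    r_small = (small.axial_1mm / small.axial_0p5mm).mean()
    r_large = (large.axial_1mm / large.axial_0p5mm).mean()
    print(f"overestimation ratio 1mm/0.5mm: {r_small:.2f} for lesions "
          f"<= 0.25 mm3 (n={len(small)}) vs {r_large:.2f} for > 1 mm3 "
          f"(n={len(large)})")

    pd.DataFrame([
        {"comparison": "axial_vs_coronal_1mm", "pearson_r": res_ac.pearson_r,
         "pearson_p": res_ac.pearson_p, "bias_mm3": res_ac.bias,
         "loa_low": res_ac.loa_low, "loa_high": res_ac.loa_high,
         "n": res_ac.n_pairs},
        {"comparison": "1mm_vs_0.5mm_axial", "pearson_r": res_th.pearson_r,
         "pearson_p": res_th.pearson_p, "bias_mm3": res_th.bias,
         "loa_low": res_th.loa_low, "loa_high": res_th.loa_high,
         "n": res_th.n_pairs},
    ]).to_csv(RESULTS / "detection_agreement.csv", index=False)

    # 2D vs 3D SNR at matched noise
    geom = geoms["axial_0p5mm"]
    ph = make_phantom(spec, geom)
    sigma = 0.01
    img2d = simulate_t2w(ph, 10.0, tr_s=3.0, noise_sigma=sigma, seed=SEED)
    img3d = simulate_t2w(ph, 9.0, tr_s=0.2, noise_sigma=sigma, seed=SEED + 1)
    lesion_roi = ph.lesion_fraction > 0.9
    paren_roi = (ph.kidney_fraction > 0.99) & (ph.lesion_fraction == 0)
    noise_roi = np.zeros(geom.shape, bool)
    noise_roi[:20, :20, :] = True
    snr2, cnr2 = snr_cnr(img2d, lesion_roi, paren_roi, noise_roi)
    snr3, cnr3 = snr_cnr(img3d, lesion_roi, paren_roi, noise_roi)
    print(f"2D TR=3s: lesion SNR {snr2:.1f}, lesion-parenchyma CNR {cnr2:.1f}")
    print(f"3D TR=0.2s: lesion SNR {snr3:.1f}, CNR {cnr3:.1f} "
          f"(ratio 2D/3D = {snr2 / snr3:.2f}, driven by T1 saturation)")
    pd.DataFrame([
        {"acquisition": "2D_tr3s", "snr": snr2, "cnr": cnr2},
        {"acquisition": "3D_tr0.2s", "snr": snr3, "cnr": cnr3},
    ]).to_csv(RESULTS / "snr_2d_vs_3d.csv", index=False)


if __name__ == "__main__":
    main()
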
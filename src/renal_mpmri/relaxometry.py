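"""Variable-flip-angle T1 mapping (DESPOT1) and blood-normalized T2 intensity.

The SPGR signal S(α) = M0 sin α (1 − E1)/(1 − E1 cos α) linearizes to

    S/sin α = E1 · (S/tan α) + M0 (1 − E1)

so an ordinary least-squares line through (S/tan α, S/sin α) yields
E1 = exp(−TR/T1) as its slope (the DESPOT1 estimator). A nonlinear SPGR
least-squares refinement is provided as the cross-check route.

T2-weighted lesion intensity is reported as a dimensionless ratio against a
blood-vessel reference ROI, which is expected to be stable across age and
treatment and thus anchors longitudinal comparisons.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geometry import AcquisitionGeometry
from .kinetics import spgr_signal
from .maps import ParameterMap

__all__ = ["VFASeries", "fit_t1_vfa", "fit_t1_nls", "normalized_t2"]


@dataclass
class VFASeries:
    """4D stack of SPGR volumes, one per flip angle (last axis)."""

    data: np.ndarray
    flip_angles_deg: tuple[float, ...]
    tr_s: float
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        angles = np.asarray(self.flip_angles_deg, dtype=float)
        if len(set(self.flip_angles_deg)) < 3:
            raise ValueError("need ≥3 distinct flip angles for a stable fit")
        if np.any(angles <= 0) or np.any(angles > 90):
            raise ValueError("flip angles must lie in (0, 90] degrees")
        if self.tr_s <= 0:
            raise ValueError("tr_s must be positive")
        if self.data.shape != self.geometry.shape + (len(angles),):
            raise ValueError("data shape must be geometry.shape + (n_angles,)")


def fit_t1_vfa(series: VFASeries, mask: np.ndarray | None = None
               ) -> tuple[ParameterMap, np.ndarray]:
    """Linearized DESPOT1 T1 fit; returns (T1 map, M0 volume).

    Per voxel, regress y = S/sin α on x = S/tan α over angles with positive
    signal; slope = E1 → T1 = −TR / ln E1, M0 = intercept / (1 − E1). Voxels
    with fewer than 3 positive-signal angles or slope outside (0, 1) are
    flagged unfittable (mask False), not raised on.
    """
    angles = np.deg2rad(np.asarray(series.flip_angles_deg, dtype=float))
    shape = series.geometry.shape
    data = series.data.reshape(-1, len(angles))
    vox_mask = (np.ones(shape, dtype=bool) if mask is None else mask.astype(bool))
    flat_mask = vox_mask.reshape(-1)

    valid = data > 0
    n_valid = valid.sum(axis=1)
    enough = flat_mask & (n_valid >= 3)

    sin_a, tan_a = np.sin(angles), np.tan(angles)
    with np.errstate(invalid="ignore", divide="ignore"):
        y = np.where(valid, data / sin_a, 0.0)
        x = np.where(valid, data / tan_a, 0.0)
    n = np.maximum(n_valid, 1)
    xm = x.sum(axis=1) / n
    ym = y.sum(axis=1) / n
    sxx = np.sum(np.where(valid, (x - xm[:, None]) ** 2, 0.0), axis=1)
    sxy = np.sum(np.where(valid, (x - xm[:, None]) * (y - ym[:, None]), 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        slope = np.where(sxx > 0, sxy / sxx, np.nan)
    intercept = ym - slope * xm

    ok = enough & np.isfinite(slope) & (slope > 0) & (slope < 1)
    t1 = np.zeros(data.shape[0])
    m0 = np.zeros(data.shape[0])
    t1[ok] = -series.tr_s / np.log(slope[ok])
    m0[ok] = intercept[ok] / (1.0 - slope[ok])

    pred = np.zeros_like(data)
    pred[ok] = spgr_signal(
        m0[ok, None], t1[ok, None], series.tr_s,
        np.rad2deg(angles)[None, :],
    )
    ss_res = np.sum(np.where(valid, (data - pred) ** 2, 0.0), axis=1)
    dm = np.sum(np.where(valid, data, 0.0), axis=1) / n
    ss_tot = np.sum(np.where(valid, (data - dm[:, None]) ** 2, 0.0), axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(ok & (ss_tot > 0), 1.0 - ss_res / ss_tot, 0.0)

    t1_map = ParameterMap(
        quantity="t1_s",
        values=t1.reshape(shape),
        geometry=series.geometry,
        mask=ok.reshape(shape),
        r2=r2.reshape(shape),
        residual_norm=np.sqrt(ss_res).reshape(shape),
        flags={
            "too_few_angles": (flat_mask & (n_valid < 3)).reshape(shape),
            "slope_out_of_range": (
                enough & ~(np.isfinite(slope) & (slope > 0) & (slope < 1))
            ).reshape(shape),
        },
    )
    return t1_map, m0.reshape(shape)


def fit_t1_nls(signals: np.ndarray, flip_angles_deg, tr_s: float,
               t1_init: float = 1.0) -> tuple[float, float]:
    """Nonlinear SPGR least squares for a single voxel; returns (t1_s, m0).

    Used as the independent cross-check of the DESPOT1 linearization.
    """
    angles = np.asarray(flip_angles_deg, dtype=float)
    s = np.asarray(signals, dtype=float)
    m0_init = s.max() / max(
        float(spgr_signal(1.0, t1_init, tr_s, angles).max()), 1e-12
    )
    popt, _ = curve_fit(
        lambda a, m0, t1: spgr_signal(m0, t1, tr_s, a),
        angles, s, p0=(m0_init, t1_init),
        bounds=([0.0, 1e-3], [np.inf, 60.0]), maxfev=5000,
    )
    return float(popt[1]), float(popt[0])


def normalized_t2(t2w_volume: np.ndarray, lesion_roi, vessel_roi) -> float:
    """Lesion T2-weighted intensity normalized to the blood-vessel reference.

    ratio = mean(lesion) / mean(vessel); gain-invariant by construction.
    Raises on empty ROIs or a non-positive vessel mean (a bad reference ROI is
    an operator error, not a statistic).
    """
    lesion_mask = np.asarray(getattr(lesion_roi, "mask", lesion_roi), dtype=bool)
    vessel_mask = np.asarray(getattr(vessel_roi, "mask", vessel_roi), dtype=bool)
    if not lesion_mask.any() or not vessel_mask.any():
        raise ValueError("lesion and vessel ROIs must both be non-empty")
    vessel_mean = float(t2w_volume[vessel_mask].mean())
    if vessel_mean <= 0:
        raise ValueError("vessel reference ROI has non-positive mean intensity")
    return float(t2w_volume[lesion_mask].mean()) / vessel_mean
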
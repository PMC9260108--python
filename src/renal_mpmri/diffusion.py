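"""ADC mapping from multi-b-value diffusion-weighted imaging.

The signal model is the mono-exponential decay S(b) = S0 · exp(−ADC · b). The
default estimator is the log-linear least-squares fit (exact on noiseless
data and the closed-form two-point solution when only two b-values exist); a
nonlinear signal-domain fit is available for the low-SNR regime where the
log transform reweights the Rician noise unfavourably. No b = 0 image is
acquired in this protocol, so S0 is always an extrapolated fit parameter.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .geometry import AcquisitionGeometry
from .maps import ParameterMap

__all__ = ["DiffusionSeries", "ROISummary", "fit_adc", "roi_mean_adc"]

ADC_RANGE = (0.0, 0.01)  # physically plausible window, mm²/s


@dataclass
class DiffusionSeries:
    """4D stack of diffusion-weighted volumes, one per b-value (last axis)."""

    data: np.ndarray
    b_values: tuple[float, ...]
    geometry: AcquisitionGeometry

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if len(b) < 2 or len(set(self.b_values)) < 2:
            raise ValueError("need ≥2 distinct b-values")
        if np.any(b < 0):
            raise ValueError("b-values must be non-negative")
        if self.data.shape != self.geometry.shape + (len(b),):
            raise ValueError("data shape must be geometry.shape + (n_b,)")


@dataclass(frozen=True)
class ROISummary:
    """Mean/sd over the fitted voxels of an ROI; sd is the sample (n−1) form."""

    mean: float
    sd: float
    n_voxels: int


def fit_adc(series: DiffusionSeries, mask: np.ndarray | None = None,
            method: str = "loglinear") -> ParameterMap:
    """Per-voxel (S0, ADC) estimates from a multi-b-value series.

    Parameters
    ----------
    series:
        The diffusion acquisition.
    mask:
        Boolean volume restricting the fit; default everywhere.
    method:
        ``"loglinear"`` (default) regresses log S on b;
        ``"nls"`` minimizes squared error in the signal domain
        (initialized from the log-linear solution).

    Returns a :class:`ParameterMap` of quantity ``adc_mm2_s`` whose ``flags``
    carry S0 (``s0`` array), non-positive-signal exclusions and range clips.
    Voxels with any non-positive signal (log-linear) are excluded and flagged,
    never raised on.
    """
    if method not in ("loglinear", "nls"):
        raise ValueError(f"unknown method {method!r}")
    b = np.asarray(series.b_values, dtype=float)
    shape = series.geometry.shape
    data = series.data.reshape(-1, len(b))
    vox_mask = (np.ones(shape, dtype=bool) if mask is None else mask.astype(bool))
    flat_mask = vox_mask.reshape(-1)

    positive = np.all(data > 0, axis=1)
    usable = flat_mask & positive

    adc = np.zeros(data.shape[0])
    s0 = np.zeros(data.shape[0])
    resid = np.zeros(data.shape[0])
    r2 = np.zeros(data.shape[0])

    # log-linear: log S = log S0 − ADC·b, solved in closed form
    logs = np.where(usable[:, None], np.log(np.where(data > 0, data, 1.0)), 0.0)
    bm = b.mean()
    denom = np.sum((b - bm) ** 2)
    ym = logs.mean(axis=1)
    slope = (logs @ (b - bm)) / denom
    adc[usable] = -slope[usable]
    s0[usable] = np.exp(ym[usable] - slope[usable] * bm)

    if method == "nls":
        lowest_ok = flat_mask & (data[:, 0] > 0)
        for i in np.flatnonzero(lowest_ok):
            p0 = (max(s0[i], data[i, 0]), float(np.clip(adc[i], *ADC_RANGE)))
            try:
                popt, _ = curve_fit(
                    lambda bb, a, d: a * np.exp(-d * bb), b, data[i],
                    p0=p0, bounds=([0.0, ADC_RANGE[0]], [np.inf, ADC_RANGE[1]]),
                    maxfev=2000,
                )
                s0[i], adc[i] = popt
            except RuntimeError:
                lowest_ok[i] = False
        usable = lowest_ok

    pred = s0[:, None] * np.exp(-adc[:, None] * b)
    ss_res = np.sum((data - pred) ** 2, axis=1)
    ss_tot = np.sum((data - data.mean(axis=1, keepdims=True)) ** 2, axis=1)
    resid[usable] = np.sqrt(ss_res[usable])
    with np.errstate(divide="ignore", invalid="ignore"):
        r2[usable] = np.where(ss_tot[usable] > 0,
                              1.0 - ss_res[usable] / ss_tot[usable], 1.0)

    out_of_range = usable & ((adc < ADC_RANGE[0]) | (adc > ADC_RANGE[1]))
    adc = np.clip(adc, *ADC_RANGE)

    fitted = usable.reshape(shape)
    return ParameterMap(
        quantity="adc_mm2_s",
        values=adc.reshape(shape),
        geometry=series.geometry,
        mask=fitted,
        r2=r2.reshape(shape),
        residual_norm=resid.reshape(shape),
        flags={
            "s0": s0.reshape(shape),
            "nonpositive_signal": (flat_mask & ~positive).reshape(shape),
            "out_of_range": out_of_range.reshape(shape),
        },
    )


def roi_mean_adc(param_map: ParameterMap, roi) -> ROISummary | None:
    """Mean/sd ADC over an ROI, restricted to successfully fitted voxels.

    ``roi`` may be a boolean volume or an object with a boolean ``mask``
    attribute (a :class:`~renal_mpmri.volumetry.LesionROI`). Returns ``None``
    (an explicit no-value) when the ROI has no fitted voxels, so degenerate
    ROIs never leak NaN arithmetic downstream.
    """
    mask = getattr(roi, "mask", roi)
    mask = np.asarray(mask, dtype=bool)
    sel = mask & param_map.mask
    n = int(sel.sum())
    if n == 0:
        return None
    vals = param_map.values[sel]
    sd = float(np.std(vals, ddof=1)) if n > 1 else 0.0
    return ROISummary(mean=float(vals.mean()), sd=sd, n_voxels=n)
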
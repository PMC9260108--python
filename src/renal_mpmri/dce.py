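"""Dynamic contrast-enhanced analysis: concentration, semi-quantitative
parameters and the Tofts K^trans fit.

The analysis follows the standard chain for SPGR DCE: detect bolus arrival on
the (ROI-mean) signal curve, invert the SPGR equation against the pre-contrast
T1 to obtain the gadolinium concentration C(t) = (R1(t) − R1₀)/r1, summarize
the curve with six semi-quantitative parameters (AUC, iAUC over the first 90 s,
wash-in and wash-out slopes, time to peak, peak concentration) and fit the
standard Tofts model for K^trans and ve against a biexponential population AIF.

AUC and iAUC are literal sums of concentrations over frames (units mM); a
Δt-scaled trapezoidal variant (mM·s) sits behind ``time_integrated=True``.
Time-to-peak is measured from bolus arrival (``from_arrival=False`` switches to
the start of the series). Peak ties break to the earliest frame.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .geometry import AcquisitionGeometry
from .kinetics import AIFModel, spgr_signal_ratio_to_e1, tofts_conc

__all__ = [
    "DynamicSeries",
    "ConcentrationCurve",
    "SemiQuantParams",
    "ToftsFit",
    "detect_bolus_arrival",
    "signal_to_concentration",
    "compute_semiquant",
    "fit_tofts",
]


@dataclass
class DynamicSeries:
    """4D dynamic acquisition (space × time, time last) with frame timing.

    ``n_dummy`` records the pre-injection dummy scans (steady-state
    preparation); ``baseline_window`` indexes the pre-arrival frames used for
    the signal baseline. ``conc_truth`` is carried by the simulator for
    round-trip validation and is absent (None) for measured data.
    """

    data: np.ndarray
    dt_s: float
    geometry: AcquisitionGeometry
    baseline_window: tuple[int, ...]
    n_dummy: int = 0
    tr_s: float = 0.039
    flip_deg: float = 40.0
    r1_relaxivity: float = 3.4
    arrival_s: float | None = None
    conc_truth: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.dt_s <= 0:
            raise ValueError("dt_s must be positive")
        if self.data.shape[:-1] != self.geometry.shape:
            raise ValueError("data shape must be geometry.shape + (n_frames,)")
        if self.n_frames < 2:
            raise ValueError("need ≥2 frames")
        if not self.baseline_window:
            raise ValueError("baseline_window must be non-empty")

    @property
    def n_frames(self) -> int:
        return self.data.shape[-1]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s

    def roi_signal(self, roi) -> np.ndarray:
        """Mean signal-time curve over an ROI (boolean volume or LesionROI)."""
        mask = np.asarray(getattr(roi, "mask", roi), dtype=bool)
        if not mask.any():
            raise ValueError("empty ROI")
        return self.data[mask].mean(axis=0)


@dataclass
class ConcentrationCurve:
    """Per-frame gadolinium concentration with its bolus-arrival index."""

    times_s: np.ndarray
    conc_mM: np.ndarray
    arrival_index: int
    flags: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.conc_mM):
            raise ValueError("times and concentrations must align")
        if not 0 <= self.arrival_index < len(self.times_s):
            raise ValueError("arrival_index outside the series")

    @property
    def dt_s(self) -> float:
        return float(self.times_s[1] - self.times_s[0])


@dataclass(frozen=True)
class SemiQuantParams:
    """The six semi-quantitative DCE descriptors; undefined entries are None.

    ``auc``/``iauc90`` are sums of concentrations over frames (mM by
    convention, mM·s when computed time-integrated).
    """

    auc: float
    iauc90: float
    wash_in_slope: float | None
    wash_out_slope: float | None
    time_to_peak_s: float
    peak_mM: float


@dataclass(frozen=True)
class ToftsFit:
    """Standard-Tofts fit result; kep = ktrans/ve."""

    ktrans_per_min: float
    ve: float
    rmse: float
    converged: bool
    ve_identifiable: bool = True

    @property
    def kep_per_min(self) -> float:
        return self.ktrans_per_min / self.ve


# ------------------------------------------------------------------- arrival
def detect_bolus_arrival(signal: np.ndarray, n_baseline: int = 5,
                         k_sd: float = 3.0, min_consecutive: int = 2
                         ) -> int | None:
    """First frame exceeding baseline mean + k·sd for ≥ ``min_consecutive`` frames.

    The baseline is the first ``n_baseline`` frames (≥3 required). Returns the
    frame index, or ``None`` when no frame qualifies (an explicit no-arrival
    result — the caller logs and excludes the lesion). A flat noiseless curve
    has zero baseline sd and never exceeds its own mean, hence no arrival.
    """
    s = np.asarray(signal, dtype=float)
    if n_baseline < 3:
        raise ValueError("need ≥3 baseline frames")
    if len(s) <= n_baseline:
        return None
    base = s[:n_baseline]
    thresh = base.mean() + k_sd * base.std(ddof=1)
    above = s > thresh
    run = 0
    for i in range(n_baseline, len(s)):
        run = run + 1 if above[i] else 0
        if run >= min_consecutive:
            return i - min_consecutive + 1
    return None


# -------------------------------------------------------------- concentration
def signal_to_concentration(
    signal: np.ndarray,
    times_s: np.ndarray,
    t1_0_s: float,
    arrival_index: int,
    r1_relaxivity: float = 3.4,
    tr_s: float = 0.039,
    flip_deg: float = 40.0,
) -> ConcentrationCurve:
    """Invert the SPGR signal equation to a concentration-time curve.

    The baseline signal is the mean over pre-arrival frames; the ratio
    S(t)/S_baseline is inverted for E1(t) → R1(t) and
    C(t) = (R1(t) − 1/T1₀)/r1. Pre-arrival concentrations are forced to zero.
    Frames whose ratio falls outside the invertible range of the SPGR curve
    are clipped to zero enhancement and counted in ``flags['clipped']``
    (low-confidence voxel/ROI).
    """
    s = np.asarray(signal, dtype=float)
    t = np.asarray(times_s, dtype=float)
    if arrival_index < 1:
        raise ValueError("need ≥1 pre-arrival baseline frame")
    if t1_0_s <= 0:
        raise ValueError("baseline T1 must be positive")
    baseline = float(s[:arrival_index].mean())
    if baseline <= 0:
        raise ValueError("non-positive baseline signal")
    e10 = np.exp(-tr_s / t1_0_s)
    e1 = spgr_signal_ratio_to_e1(s / baseline, e10, flip_deg)
    invalid = ~((e1 > 0.0) & (e1 < 1.0))
    e1 = np.clip(e1, 1e-12, e10)  # clip to zero enhancement at worst
    r1 = -np.log(e1) / tr_s
    conc = (r1 - 1.0 / t1_0_s) / r1_relaxivity
    conc[:arrival_index] = 0.0
    n_clipped = int(invalid[arrival_index:].sum())
    return ConcentrationCurve(
        times_s=t, conc_mM=conc, arrival_index=arrival_index,
        flags={"clipped": n_clipped, "low_confidence": n_clipped > 0},
    )


# ---------------------------------------------------------------- semi-quant
def compute_semiquant(curve: ConcentrationCurve,
                      iauc_window_s: float = 90.0,
                      time_integrated: bool = False,
                      from_arrival: bool = True) -> SemiQuantParams:
    """The six semi-quantitative parameters of a concentration curve.

    auc sums C over all frames; iauc90 sums C over frames with
    t ∈ [t_arrival, t_arrival + 90 s]. Wash-in is the chord slope from arrival
    to peak, wash-out the OLS slope from peak to the last frame (positive
    slopes allowed, sign preserved). When the peak sits at the arrival frame
    wash-in is undefined; at the last frame wash-out is undefined — both are
    explicit ``None``, never NaN.
    """
    c = np.asarray(curve.conc_mM, dtype=float)
    t = np.asarray(curve.times_s, dtype=float)
    i0 = curve.arrival_index
    w = curve.dt_s if time_integrated else 1.0

    auc = float(c.sum() * w)
    in_window = (t >= t[i0]) & (t <= t[i0] + iauc_window_s)
    iauc = float(c[in_window].sum() * w)

    # peak searched from arrival onward; earliest maximum by argmax convention
    ipeak = i0 + int(np.argmax(c[i0:]))
    peak = float(c[ipeak])
    t_ref = t[i0] if from_arrival else t[0]
    ttp = float(t[ipeak] - t_ref)

    if ipeak > i0:
        wash_in = float((c[ipeak] - c[i0]) / (t[ipeak] - t[i0]))
    else:
        wash_in = None

    if ipeak < len(c) - 1:
        tt, cc = t[ipeak:], c[ipeak:]
        tm = tt.mean()
        wash_out = float(np.sum((tt - tm) * (cc - cc.mean())) / np.sum((tt - tm) ** 2))
    else:
        wash_out = None

    return SemiQuantParams(
        auc=auc, iauc90=iauc, wash_in_slope=wash_in, wash_out_slope=wash_out,
        time_to_peak_s=ttp, peak_mM=peak,
    )


# --------------------------------------------------------------------- Tofts
def fit_tofts(
    curve: ConcentrationCurve,
    aif: AIFModel,
    bounds: tuple[tuple[float, float], tuple[float, float]] = ((0.0, 5.0), (0.01, 1.0)),
    multistart: int = 5,
) -> ToftsFit:
    """Least-squares standard-Tofts fit of a tissue concentration curve.

    The model is the closed-form biexponential-AIF solution with the bolus
    aligned to the curve's arrival index. ``multistart`` log-spaced K^trans
    initializations (ve starting mid-range) are run and the best-RMSE
    convergent solution wins; the convergence flag is honest. An all-zero
    curve returns K^trans = 0 with ve marked unidentifiable.
    """
    c = np.asarray(curve.conc_mM, dtype=float)
    t = np.asarray(curve.times_s, dtype=float)
    arrival_s = float(t[curve.arrival_index])
    post = t >= arrival_s
    if post.sum() < 10:
        raise ValueError("need ≥10 post-arrival frames for a Tofts fit")
    if np.allclose(c, 0.0):
        return ToftsFit(ktrans_per_min=0.0, ve=float(bounds[1][0]), rmse=0.0,
                        converged=True, ve_identifiable=False)

    (kt_lo, kt_hi), (ve_lo, ve_hi) = bounds

    def resid(p):
        return tofts_conc(t, p[0], p[1], aif, arrival_s=arrival_s) - c

    best = None
    kt_inits = np.geomspace(max(kt_lo, 1e-3), min(kt_hi, 2.0), multistart)
    for kt0 in kt_inits:
        try:
            sol = least_squares(
                resid, x0=[kt0, 0.3],
                bounds=([kt_lo, ve_lo], [kt_hi, ve_hi]),
                method="trf", xtol=1e-12, ftol=1e-12, gtol=1e-12,
            )
        except Exception:
            continue
        rmse = float(np.sqrt(np.mean(sol.fun**2)))
        if best is None or rmse < best[0]:
            best = (rmse, sol)
    if best is None:
        return ToftsFit(ktrans_per_min=np.nan, ve=np.nan, rmse=np.inf,
                        converged=False)
    rmse, sol = best
    return ToftsFit(
        ktrans_per_min=float(sol.x[0]), ve=float(sol.x[1]), rmse=rmse,
        converged=bool(sol.success),
    )
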
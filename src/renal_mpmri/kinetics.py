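"""Signal and pharmacokinetic forward models shared by the simulator and fits.

Contains the spoiled-gradient-echo (SPGR) steady-state signal equation used by
both the variable-flip-angle T1 stage and the dynamic contrast-enhanced (DCE)
stage, a population biexponential arterial input function (AIF), and the
standard Tofts tissue-concentration model

    Ct(t) = K^trans ∫0..t Cp(τ) · exp(−kep (t − τ)) dτ,     kep = K^trans / ve,

evaluated both in exact closed form (biexponential AIF) and by numerical
convolution; the two routes serve as mutual oracles.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "AIFModel",
    "spgr_signal",
    "spgr_signal_ratio_to_e1",
    "tofts_conc",
    "tofts_conc_numeric",
]


def spgr_signal(m0, t1_s, tr_s: float, flip_deg):
    """Steady-state spoiled gradient-echo signal.

    S = M0 · sin α · (1 − E1) / (1 − E1 cos α),  E1 = exp(−TR/T1).

    Accepts scalars or broadcastable arrays for ``m0``, ``t1_s`` and
    ``flip_deg``; TE decay is assumed folded into ``m0`` (constant per series).
    """
    if tr_s <= 0:
        raise ValueError("tr_s must be positive")
    flip = np.deg2rad(np.asarray(flip_deg, dtype=float))
    if np.any(flip <= 0) or np.any(flip > np.pi / 2):
        raise ValueError("flip angles must lie in (0, 90] degrees")
    e1 = np.exp(-tr_s / np.asarray(t1_s, dtype=float))
    return np.asarray(m0) * np.sin(flip) * (1.0 - e1) / (1.0 - e1 * np.cos(flip))


def spgr_signal_ratio_to_e1(ratio, e1_baseline, flip_deg: float):
    """Invert a baseline-relative SPGR signal ratio to E1(t).

    Given r = S(t)/S_baseline, the M0·sinα factor cancels and

        r · (1 − E10)/(1 − E10 cosα) = (1 − E1)/(1 − E1 cosα)

    which is solved for E1. Values of the rescaled ratio outside (0, 1) are
    outside the invertible range of the SPGR curve and yield E1 outside (0, 1);
    callers should flag and clip those.
    """
    cosa = np.cos(np.deg2rad(flip_deg))
    g = np.asarray(ratio, dtype=float) * (1.0 - e1_baseline) / (
        1.0 - e1_baseline * cosa
    )
    return (1.0 - g) / (1.0 - g * cosa)


@dataclass(frozen=True)
class AIFModel:
    """Population biexponential plasma input function.

    Cp(t) = D · (a1 e^(−m1 t) + a2 e^(−m2 t)) for t ≥ arrival, 0 before, with
    t in minutes since bolus arrival, D the injected dose in mmol/kg and
    amplitudes in kg/L so Cp is in mM. Defaults are the classic biexponential
    Gd-DTPA parametrization with the study dose of 0.27 mmol/kg.
    """

    dose_mmol_per_kg: float = 0.27
    a1_kg_per_l: float = 3.99
    a2_kg_per_l: float = 4.78
    m1_per_min: float = 0.144
    m2_per_min: float = 0.0111

    def __post_init__(self) -> None:
        if self.dose_mmol_per_kg < 0:
            raise ValueError("dose must be non-negative")
        if min(self.a1_kg_per_l, self.a2_kg_per_l) < 0:
            raise ValueError("AIF amplitudes must be non-negative")
        if min(self.m1_per_min, self.m2_per_min) < 0:
            raise ValueError("AIF decay rates must be non-negative")

    @property
    def terms(self) -> tuple[tuple[float, float], ...]:
        return (
            (self.a1_kg_per_l, self.m1_per_min),
            (self.a2_kg_per_l, self.m2_per_min),
        )

    def plasma_conc(self, t_min) -> np.ndarray:
        """Cp in mM at ``t_min`` minutes after bolus arrival (0 for t < 0)."""
        t = np.asarray(t_min, dtype=float)
        cp = sum(a * np.exp(-m * np.maximum(t, 0.0)) for a, m in self.terms)
        return np.where(t < 0.0, 0.0, self.dose_mmol_per_kg * cp)


def tofts_conc(t_s, ktrans_per_min: float, ve: float, aif: AIFModel,
               arrival_s: float = 0.0) -> np.ndarray:
    """Closed-form Tofts tissue concentration (mM) for a biexponential AIF.

    With Cp(t) = D Σ aᵢ e^(−mᵢ t), the convolution integral evaluates exactly:

        Ct(t) = K^trans D Σ aᵢ (e^(−kep t) − e^(−mᵢ t)) / (mᵢ − kep)

    falling back to the aᵢ t e^(−mᵢ t) limit where mᵢ ≈ kep. Times are in
    seconds on the scanner clock; ``arrival_s`` shifts the bolus.
    """
    if ktrans_per_min < 0:
        raise ValueError("ktrans must be non-negative")
    if not 0.0 < ve <= 1.0:
        raise ValueError("ve must lie in (0, 1]")
    t = (np.asarray(t_s, dtype=float) - arrival_s) / 60.0  # minutes post-arrival
    tpos = np.maximum(t, 0.0)
    kep = ktrans_per_min / ve
    total = np.zeros_like(tpos)
    for a, m in aif.terms:
        if abs(m - kep) < 1e-9:
            total = total + a * tpos * np.exp(-m * tpos)
        else:
            total = total + a * (np.exp(-kep * tpos) - np.exp(-m * tpos)) / (m - kep)
    ct = ktrans_per_min * aif.dose_mmol_per_kg * total
    return np.where(t < 0.0, 0.0, ct)


def tofts_conc_numeric(t_s, ktrans_per_min: float, ve: float, aif: AIFModel,
                       arrival_s: float = 0.0, dt_s: float = 0.1) -> np.ndarray:
    """Tofts concentration by trapezoidal numerical convolution.

    Independent route used to validate :func:`tofts_conc`; integrates
    Cp(τ) e^(−kep (t−τ)) on a uniform ``dt_s`` grid from arrival to each
    requested time.
    """
    if not 0.0 < ve <= 1.0:
        raise ValueError("ve must lie in (0, 1]")
    t = np.atleast_1d(np.asarray(t_s, dtype=float)) - arrival_s
    kep = ktrans_per_min / ve
    out = np.zeros_like(t)
    for i, ti in enumerate(t):
        if ti <= 0:
            continue
        n = max(int(np.ceil(ti / dt_s)), 1)
        tau = np.linspace(0.0, ti, n + 1)  # seconds post-arrival
        integrand = aif.plasma_conc(tau / 60.0) * np.exp(-kep * (ti - tau) / 60.0)
        out[i] = ktrans_per_min * np.trapezoid(integrand, tau / 60.0)
    return out.reshape(np.shape(t_s)) if np.ndim(t_s) else float(out[0])
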
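"""Forward simulation of the study's four acquisitions from phantom maps.

All simulators are deterministic under a fixed seed and share the Rician
magnitude noise model: the complex signal receives independent Gaussian noise
of scale ``noise_sigma`` on both channels before the magnitude is taken, which
reproduces the upward noise-floor bias of low-SNR magnitude MRI. ``noise_sigma``
is an absolute signal scale; :func:`sigma_for_snr` converts an SNR quoted
against a reference signal.
"""

from __future__ import annotations

import numpy as np

from .dce import DynamicSeries
from .diffusion import DiffusionSeries
from .kinetics import AIFModel, spgr_signal, tofts_conc
from .relaxometry import VFASeries

__all__ = [
    "add_rician_noise",
    "sigma_for_snr",
    "simulate_dwi",
    "simulate_vfa",
    "simulate_t2w",
    "simulate_dce",
]


def sigma_for_snr(reference_signal: float, snr: float) -> float:
    """Noise scale giving the requested SNR at ``reference_signal``."""
    if snr <= 0:
        raise ValueError("snr must be positive")
    return float(reference_signal) / snr


def add_rician_noise(signal: np.ndarray, sigma: float,
                     rng: np.random.Generator) -> np.ndarray:
    """Magnitude of (S + n1) + i·n2 with n1, n2 ~ N(0, sigma²)."""
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    if sigma == 0:
        return np.asarray(signal, dtype=float).copy()
    s = np.asarray(signal, dtype=float)
    return np.hypot(s + rng.normal(0.0, sigma, s.shape),
                    rng.normal(0.0, sigma, s.shape))


def simulate_dwi(maps, b_values, noise_sigma: float = 0.0,
                 seed: int | None = None) -> DiffusionSeries:
    """Mono-exponential diffusion-weighted series S = pd · exp(−b · ADC).

    ``maps`` is a phantom map stack (dict with at least ``pd`` and ``adc``)
    plus the geometry on a :class:`~renal_mpmri.phantom.PhantomResult`, or any
    object with ``.maps`` and ``.geometry``.
    """
    b = np.asarray(b_values, dtype=float)
    if np.any(b < 0):
        raise ValueError("b-values must be non-negative")
    if b.ndim != 1 or len(b) < 2 or np.any(np.diff(b) <= 0):
        raise ValueError("b_values must be strictly increasing with ≥2 entries")
    pd_map, adc = maps.maps["pd"], maps.maps["adc"]
    signal = pd_map[..., None] * np.exp(-adc[..., None] * b)
    rng = np.random.default_rng(seed)
    data = add_rician_noise(signal, noise_sigma, rng)
    return DiffusionSeries(data=data, b_values=tuple(b), geometry=maps.geometry)


def simulate_vfa(maps, flip_angles_deg, tr_s: float,
                 noise_sigma: float = 0.0, seed: int | None = None) -> VFASeries:
    """Variable-flip-angle SPGR series over the phantom's pd and T1 maps."""
    angles = np.asarray(flip_angles_deg, dtype=float)
    if np.any(angles <= 0) or np.any(angles > 90):
        raise ValueError("flip angles must lie in (0, 90] degrees")
    pd_map, t1 = maps.maps["pd"], maps.maps["t1"]
    signal = spgr_signal(pd_map[..., None], t1[..., None], tr_s, angles)
    rng = np.random.default_rng(seed)
    data = add_rician_noise(signal, noise_sigma, rng)
    return VFASeries(data=data, flip_angles_deg=tuple(angles), tr_s=tr_s,
                     geometry=maps.geometry)


def simulate_t2w(maps, te_ms: float, tr_s: float | None = None,
                 noise_sigma: float = 0.0, seed: int | None = None) -> np.ndarray:
    """T2-weighted fast-spin-echo volume, mono-exponential TE weighting.

    S = pd · exp(−TE/T2), optionally saturation-weighted by (1 − exp(−TR/T1))
    when ``tr_s`` is given (needed to compare repetition-time regimes, e.g.
    the 2D TR = 3 s vs 3D TR = 0.2 s protocols).
    """
    if te_ms < 0:
        raise ValueError("te_ms must be non-negative")
    signal = maps.maps["pd"] * np.exp(-te_ms / maps.maps["t2"])
    if tr_s is not None:
        signal = signal * (1.0 - np.exp(-tr_s / maps.maps["t1"]))
    rng = np.random.default_rng(seed)
    return add_rician_noise(signal, noise_sigma, rng)


def simulate_dce(
    maps,
    aif: AIFModel,
    dt_s: float = 5.0,
    n_frames: int = 50,
    arrival_s: float = 25.0,
    n_dummy: int = 40,
    r1_relaxivity: float = 3.4,
    tr_s: float = 0.039,
    flip_deg: float = 40.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
) -> DynamicSeries:
    """Dynamic contrast-enhanced SPGR series from K^trans/ve/T1 maps.

    Tissue concentration follows the closed-form Tofts solution; the frame
    signal is the SPGR equation at R1(t) = 1/T1₀ + r1 · Ct(t). Frames before
    ``arrival_s`` carry baseline signal only. ``n_dummy`` pre-injection dummy
    scans are bookkeeping metadata (the steady state is assumed established).
    """
    if dt_s <= 0:
        raise ValueError("dt_s must be positive")
    if n_frames < 2:
        raise ValueError("n_frames must be ≥ 2")
    if not 0.0 <= arrival_s < n_frames * dt_s:
        raise ValueError("arrival must fall within the acquired series")
    pd_map = maps.maps["pd"]
    t1 = maps.maps["t1"]
    ktrans = maps.maps["ktrans"]
    ve = maps.maps["ve"]
    if np.any((ktrans > 0) & (ve <= 0)):
        raise ValueError("ktrans > 0 with kep = 0 is inconsistent tissue")

    times = np.arange(n_frames) * dt_s
    shape = pd_map.shape
    conc = np.zeros(shape + (n_frames,))
    # closed-form Ct voxelwise over unique (ktrans, ve) pairs to stay cheap on
    # piecewise-constant phantoms
    pairs = np.stack([ktrans.ravel(), ve.ravel()], axis=1)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    flat = conc.reshape(-1, n_frames)
    for idx, (kt, v) in enumerate(uniq):
        if kt == 0.0:
            continue
        curve = tofts_conc(times, float(kt), float(v), aif, arrival_s=arrival_s)
        flat[inverse == idx] = curve
    conc = flat.reshape(shape + (n_frames,))

    r1 = 1.0 / t1[..., None] + r1_relaxivity * conc
    signal = spgr_signal(pd_map[..., None], 1.0 / r1, tr_s, flip_deg)
    rng = np.random.default_rng(seed)
    data = add_rician_noise(signal, noise_sigma, rng)
    n_baseline = int(np.floor(arrival_s / dt_s))
    return DynamicSeries(
        data=data,
        dt_s=dt_s,
        n_dummy=n_dummy,
        baseline_window=tuple(range(max(n_baseline, 1))),
        geometry=maps.geometry,
        tr_s=tr_s,
        flip_deg=flip_deg,
        r1_relaxivity=r1_relaxivity,
        arrival_s=arrival_s,
        conc_truth=conc,
    )
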
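"""DCE analysis: arrival detection, concentration conversion, semi-quantitative
parameters and the Tofts fit."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from renal_mpmri.dce import (
    ConcentrationCurve,
    compute_semiquant,
    detect_bolus_arrival,
    fit_tofts,
    signal_to_concentration,
)
from renal_mpmri.kinetics import AIFModel, spgr_signal, tofts_conc
from renal_mpmri.simulate import simulate_dce


def paper_curve():
    """The piecewise-linear fixture: arrival frame 3, dt 5 s.

    Zero through frame 2, linear rise to 1.0 mM at frame 13, linear fall to
    0.5 mM at frame 49.
    """
    c = np.zeros(50)
    c[3:14] = np.linspace(0.0, 1.0, 11)
    c[14:] = 1.0 - np.arange(1, 36 + 1) * (0.5 / 36.0)
    return ConcentrationCurve(times_s=np.arange(50) * 5.0, conc_mM=c,
                              arrival_index=3)


class TestArrivalDetection:
    def test_flat_noiseless_curve_has_no_arrival(self):
        assert detect_bolus_arrival(np.ones(50)) is None

    def test_exact_step_detected_at_step_frame(self):
        s = np.zeros(50)
        s[8:] = 10.0
        assert detect_bolus_arrival(s, n_baseline=8) == 8

    def test_requires_three_baseline_frames(self):
        with pytest.raises(ValueError):
            detect_bolus_arrival(np.ones(50), n_baseline=2)

    def test_single_spike_not_mistaken_for_arrival(self, rng):
        s = rng.normal(1.0, 0.01, 50)
        s[20] = 5.0  # isolated outlier, min_consecutive = 2 rejects it
        assert detect_bolus_arrival(s) != 20

    def test_simulated_arrival_recovered_within_one_frame_at_snr20(self, aif, rng):
        # ROI-mean curves (the analysis unit for lesions), 25 voxels, SNR 20
        t = np.arange(50) * 5.0
        ct = tofts_conc(t, 0.33, 0.3, aif, arrival_s=25.0)
        r1 = 1.0 / 1.5 + 3.4 * ct
        sig = spgr_signal(1.0, 1.0 / r1, 0.039, 40.0)
        sigma = sig[0] / 20.0
        hits = 0
        n_rep = 300
        for _ in range(n_rep):
            noise = np.hypot(
                sig[None, :] + rng.normal(0, sigma, (25, 50)),
                rng.normal(0, sigma, (25, 50)),
            ).mean(axis=0)
            a = detect_bolus_arrival(noise, n_baseline=5)
            if a is not None and abs(a - 5) <= 1:
                hits += 1
        assert hits / n_rep >= 0.95


class TestSignalToConcentration:
    def test_constant_signal_maps_to_zero_concentration(self):
        t = np.arange(50) * 5.0
        curve = signal_to_concentration(np.full(50, 0.07), t, 1.5, 5)
        np.testing.assert_allclose(curve.conc_mM, 0.0, atol=1e-12)

    def test_round_trip_through_simulator(self, uniform_phantom, aif):
        ph = uniform_phantom(t1=1.5, ktrans=0.33, ve=0.3)
        dyn = simulate_dce(ph, aif)
        curve = signal_to_concentration(
            dyn.data[0, 0, 0], dyn.times_s, 1.5, arrival_index=5,
            r1_relaxivity=dyn.r1_relaxivity, tr_s=dyn.tr_s,
            flip_deg=dyn.flip_deg,
        )
        truth = dyn.conc_truth[0, 0, 0]
        assert np.max(np.abs(curve.conc_mM - truth)) / truth.max() < 1e-8

    def test_peak_concentration_linear_in_dose(self, uniform_phantom):
        peaks = []
        for dose in (0.27, 0.54):
            ph = uniform_phantom(t1=1.5, ktrans=0.2, ve=0.3)
            dyn = simulate_dce(ph, AIFModel(dose_mmol_per_kg=dose))
            curve = signal_to_concentration(
                dyn.data[0, 0, 0], dyn.times_s, 1.5, 5
            )
            peaks.append(curve.conc_mM.max())
        assert peaks[1] == pytest.approx(2.0 * peaks[0], rel=1e-6)

    def test_uninvertible_frames_flagged_and_clipped(self):
        t = np.arange(20) * 5.0
        s = np.full(20, 0.07)
        s[10] = 1e4  # far beyond the SPGR saturation ceiling
        curve = signal_to_concentration(s, t, 1.5, 5)
        assert curve.flags["clipped"] == 1
        assert curve.flags["low_confidence"]
        assert np.isfinite(curve.conc_mM).all()


class TestSemiQuant:
    def test_piecewise_linear_fixture_closed_form(self):
        sq = compute_semiquant(paper_curve())
        assert sq.peak_mM == pytest.approx(1.0)
        assert sq.time_to_peak_s == pytest.approx(50.0)
        assert sq.wash_in_slope == pytest.approx(0.02)
        assert sq.wash_out_slope == pytest.approx(-1.0 / 360.0, rel=1e-9)
        # 19 samples in [15 s, 105 s]: rise 0..1.0 sums to 5.5, the 8
        # post-peak linear-fall samples sum to 7.5
        assert sq.iauc90 == pytest.approx(13.0, rel=1e-12)
        assert sq.auc == pytest.approx(32.25, rel=1e-12)

    def test_constant_post_arrival_curve(self):
        c = np.zeros(50)
        c[5:] = 0.8
        curve = ConcentrationCurve(np.arange(50) * 5.0, c, arrival_index=5)
        sq = compute_semiquant(curve)
        assert sq.wash_in_slope is None  # peak ties at arrival, earliest wins
        assert sq.wash_out_slope == pytest.approx(0.0, abs=1e-15)
        assert sq.time_to_peak_s == 0.0

    def test_monotone_rise_to_last_frame(self):
        c = np.concatenate([np.zeros(5), np.linspace(0.01, 1.0, 45)])
        curve = ConcentrationCurve(np.arange(50) * 5.0, c, arrival_index=5)
        sq = compute_semiquant(curve)
        assert sq.wash_out_slope is None
        assert sq.time_to_peak_s == pytest.approx((49 - 5) * 5.0)

    def test_time_integrated_variant_scales_by_dt(self):
        sq = compute_semiquant(paper_curve())
        sq_dt = compute_semiquant(paper_curve(), time_integrated=True)
        assert sq_dt.auc == pytest.approx(5.0 * sq.auc)
        assert sq_dt.iauc90 == pytest.approx(5.0 * sq.iauc90)

    @given(
        st.lists(st.floats(0.0, 5.0), min_size=12, max_size=50),
        st.integers(1, 5),
    )
    @settings(max_examples=100, deadline=None)
    def test_invariants_on_nonnegative_curves(self, values, arrival):
        c = np.asarray(values)
        c[:arrival] = 0.0
        curve = ConcentrationCurve(np.arange(len(c)) * 5.0, c, arrival)
        sq = compute_semiquant(curve)
        assert sq.iauc90 <= sq.auc + 1e-12
        assert sq.peak_mM >= c[arrival]
        assert sq.time_to_peak_s >= 0.0


class TestToftsFit:
    def test_zero_curve_gives_zero_ktrans_unidentifiable_ve(self, aif):
        curve = ConcentrationCurve(np.arange(50) * 5.0, np.zeros(50), 5)
        fit = fit_tofts(curve, aif)
        assert fit.ktrans_per_min == 0.0
        assert not fit.ve_identifiable

    @pytest.mark.parametrize("ktrans", [0.04, 0.33])
    def test_noiseless_recovery_within_1pct(self, aif, ktrans):
        t = np.arange(50) * 5.0
        ct = tofts_conc(t, ktrans, 0.30, aif, arrival_s=25.0)
        curve = ConcentrationCurve(t, ct, 5)
        fit = fit_tofts(curve, aif)
        assert fit.converged
        assert fit.ktrans_per_min == pytest.approx(ktrans, rel=0.01)
        assert fit.ve == pytest.approx(0.30, rel=0.01)

    def test_requires_ten_post_arrival_frames(self, aif):
        curve = ConcentrationCurve(np.arange(12) * 5.0, np.ones(12), 5)
        with pytest.raises(ValueError, match="post-arrival"):
            fit_tofts(curve, aif)

    def test_ktrans_ordering_preserved_under_noise(self, aif, rng):
        # the cystic (0.04) vs solid (0.33) contrast survives SNR 20 noise
        t = np.arange(50) * 5.0
        sigs = {}
        for kt in (0.04, 0.33):
            ct = tofts_conc(t, kt, 0.3, aif, arrival_s=25.0)
            r1 = 1.0 / 1.5 + 3.4 * ct
            sigs[kt] = spgr_signal(1.0, 1.0 / r1, 0.039, 40.0)
        sigma = sigs[0.33][0] / 20.0
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            est = {}
            for kt, sig in sigs.items():
                noisy = np.hypot(sig + rng.normal(0, sigma, 50),
                                 rng.normal(0, sigma, 50))
                curve = signal_to_concentration(noisy, t, 1.5, 5)
                est[kt] = fit_tofts(curve, aif).ktrans_per_min
            if est[0.33] > est[0.04]:
                wins += 1
        assert wins / n_rep >= 0.95
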
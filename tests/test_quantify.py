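"""31P-MRS quantification: time base, concentrations, pH, CK-equilibrium ADP."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import pmrflux as pm
from pmrflux.quantify import (
    AcquisitionProtocol, CKParams, PhCalibration, ProtocolError,
    absolute_concentrations, adp_from_ck, bin_durations, bin_midpoints,
    calibrate_tcr, default_tcr, ph_from_shift, shift_from_ph,
)
from pmrflux.quantify import CalibrationError


class TestProtocolTimeBase:
    def test_default_protocol_bin_count_and_fid_total(self, protocol):
        assert protocol.n_bins == 1 + 6 + 11
        assert protocol.total_fids == 768
        protocol.validate_totals()  # 64 + 192 + 512

    def test_stim_bins_give_60s_resolution(self, protocol):
        mids = bin_midpoints(protocol)
        stim = mids[1:7]
        assert np.allclose(np.diff(stim), 60.0)
        # first stimulation bin spans 60 s, midpoint 30 s after stim onset
        assert stim[0] == pytest.approx(protocol.phase_onset("stim") + 30.0)

    def test_single_fid_packet_midpoint(self):
        proto = AcquisitionProtocol(rest_packets=(1,), stim_packets=(4, 4, 4, 4),
                                    recovery_packets=(4, 4, 4, 4))
        assert bin_midpoints(proto)[0] == pytest.approx(0.9375)

    def test_last_recovery_bin_is_180s_ending_at_protocol_end(self, protocol):
        mids = bin_midpoints(protocol)
        durs = bin_durations(protocol)
        assert durs[-1] == pytest.approx(96 * 1.875)
        total = protocol.phase_onset("recovery") + protocol.phase_duration("recovery")
        assert mids[-1] == pytest.approx(total - 90.0)

    def test_phase_durations_sum_over_bins(self, protocol):
        durs = bin_durations(protocol)
        assert durs[1:7].sum() == pytest.approx(protocol.phase_duration("stim")) == 360.0
        assert durs[7:].sum() == pytest.approx(protocol.phase_duration("recovery")) == 960.0

    def test_bad_packet_totals_raise(self):
        proto = AcquisitionProtocol(stim_packets=(32,) * 5)
        with pytest.raises(ProtocolError):
            proto.validate_totals()


def _peak_tables(protocol, pcr_area=443.0, beta_area=100.0, factors=1.0):
    n = protocol.n_bins
    shift = shift_from_ph(7.0)
    peaks = pd.DataFrame({
        "bin_index": np.arange(n),
        "phase": protocol.phase_of_bin(),
        "pme": np.zeros(n),
        "pi": np.full(n, 40.0),
        "pcr": np.full(n, pcr_area),
        "atp_gamma": np.full(n, beta_area),
        "atp_alpha": np.full(n, beta_area),
        "atp_beta": np.full(n, beta_area),
        "pi_shift_ppm": np.full(n, shift),
    })
    relaxed = peaks.iloc[[0]].copy()
    for col in ("pi", "pcr", "atp_gamma", "atp_alpha", "atp_beta"):
        relaxed[col] = relaxed[col] * factors
    return peaks, relaxed


class TestAbsoluteConcentrations:
    def test_anchoring_reproduces_resting_pcr(self, protocol):
        # unit saturation factors, beta-ATP 100 vs PCr 443 anchored at 7.22
        peaks, relaxed = _peak_tables(protocol)
        series = absolute_concentrations(peaks, relaxed, atp_ref=7.22)
        rest = series[series["phase"] == "rest"]
        assert rest["pcr"].iloc[0] == pytest.approx(443 * 7.22 / 100, rel=1e-12)
        assert rest["pcr"].iloc[0] == pytest.approx(32.0, rel=0.01)
        assert rest["atp"].iloc[0] == pytest.approx(7.22)

    def test_zero_areas_stay_zero(self, protocol):
        peaks, relaxed = _peak_tables(protocol)
        for col in ("pi", "pcr"):
            peaks[col] = 0.0
            relaxed[col] = 0.0
        series = absolute_concentrations(peaks, relaxed, atp_ref=7.22)
        assert (series["pcr"] == 0).all() and (series["pi"] == 0).all()

    def test_scale_invariance_of_ratio_anchoring(self, protocol):
        peaks, relaxed = _peak_tables(protocol)
        a = absolute_concentrations(peaks, relaxed, atp_ref=7.22)
        scaled = peaks.copy()
        for col in ("pi", "pcr", "atp_gamma", "atp_alpha", "atp_beta"):
            scaled[col] = peaks[col] * 2.0
        b = absolute_concentrations(scaled, relaxed, atp_ref=7.22)
        # doubling every raw area (relaxed spectrum untouched changes the
        # saturation factor, but anchoring cancels it) leaves output fixed
        pd.testing.assert_frame_equal(a, b)

    def test_saturation_correction_with_unit_factors_is_identity(self, protocol):
        peaks, relaxed = _peak_tables(protocol, factors=1.0)
        a = absolute_concentrations(peaks, relaxed, atp_ref=7.22)
        # feeding back already-corrected data with factors 1 changes nothing
        peaks2 = peaks.copy()
        b = absolute_concentrations(peaks2, relaxed, atp_ref=7.22)
        pd.testing.assert_frame_equal(a, b)

    def test_saturation_factors_applied_per_metabolite(self, protocol):
        peaks, relaxed = _peak_tables(protocol, factors=2.0)
        # relaxed pcr twice the saturated one -> concentrations unchanged
        # relative to beta-ATP whose factor is also 2
        series = absolute_concentrations(peaks, relaxed, atp_ref=7.22)
        assert series["pcr"].iloc[0] == pytest.approx(443 * 7.22 / 100)

    def test_zero_saturated_rest_area_raises(self, protocol):
        peaks, relaxed = _peak_tables(protocol)
        peaks["pi"] = 0.0  # relaxed pi still nonzero
        with pytest.raises(ZeroDivisionError):
            absolute_concentrations(peaks, relaxed, atp_ref=7.22)


class TestPh:
    def test_midpoint_of_calibration_gives_pk(self):
        assert ph_from_shift(4.48) == pytest.approx(6.75)

    def test_known_shift(self):
        assert ph_from_shift(4.90) == pytest.approx(7.0646, abs=1e-3)

    @pytest.mark.parametrize("shift", [3.27, 5.69, 3.0, 6.0])
    def test_out_of_range_shift_raises(self, shift):
        with pytest.raises(CalibrationError):
            ph_from_shift(shift)

    @given(st.floats(min_value=3.28, max_value=5.68))
    @settings(max_examples=50, derandomize=True)
    def test_shift_ph_round_trip(self, shift):
        assert shift_from_ph(ph_from_shift(shift)) == pytest.approx(shift, abs=1e-10)

    def test_monotone_increasing_in_shift(self):
        shifts = np.linspace(3.3, 5.65, 200)
        assert (np.diff(ph_from_shift(shifts)) > 0).all()


class TestAdpFromCk:
    CK = CKParams(tcr=37.7)

    def test_zero_free_creatine_gives_zero_adp(self):
        ck = CKParams(tcr=32.0)
        assert adp_from_ck(32.0, 7.22, 7.06, ck) == 0.0

    def test_unit_ph_drop_divides_adp_by_ten(self):
        hi = adp_from_ck(20.0, 7.22, 7.0, self.CK)
        lo = adp_from_ck(20.0, 7.22, 6.0, self.CK)
        assert lo == pytest.approx(hi / 10.0, rel=1e-12)

    def test_strictly_decreasing_in_pcr_increasing_in_ph(self):
        pcr = np.linspace(5, 37, 100)
        vals = adp_from_ck(pcr, 7.22, 7.0, self.CK)
        assert (np.diff(vals) < 0).all()
        ph = np.linspace(6.0, 7.5, 100)
        vals = adp_from_ck(20.0, 7.22, ph, self.CK)
        assert (np.diff(vals) > 0).all()

    def test_tcr_below_pcr_raises(self):
        with pytest.raises(ValueError):
            adp_from_ck(38.0, 7.22, 7.0, self.CK)

    def test_zero_pcr_raises(self):
        with pytest.raises(ZeroDivisionError):
            adp_from_ck(0.0, 7.22, 7.0, self.CK)


class TestCalibrateTcr:
    def test_round_trip_reproduces_resting_adp(self):
        # resting state as in a healthy control muscle
        tcr = calibrate_tcr(32.0, 7.22, 7.06, 8.8)
        ck = CKParams(tcr=tcr)
        assert adp_from_ck(32.0, 7.22, 7.06, ck) == pytest.approx(8.8, rel=1e-9)
        # the implied pool puts resting PCr near 85% of total creatine
        assert 32.0 / tcr == pytest.approx(0.85, abs=0.02)

    def test_zero_adp_returns_pcr(self):
        assert calibrate_tcr(32.0, 7.22, 7.06, 0.0) == pytest.approx(32.0)

    def test_doubling_k_halves_free_creatine(self):
        cr1 = calibrate_tcr(32.0, 7.22, 7.06, 8.8, ck_k=1.67e9) - 32.0
        cr2 = calibrate_tcr(32.0, 7.22, 7.06, 8.8, ck_k=2 * 1.67e9) - 32.0
        assert cr2 == pytest.approx(2 * cr1, rel=1e-12)

    def test_fallback_pool_fraction(self):
        assert default_tcr(32.0) == pytest.approx(32.0 / 0.85)


class TestBuildSeries:
    def test_end_to_end_round_trip_from_simulated_bout(self, deep_bout):
        # series -> synthetic peak areas -> quantification recovers it
        truth = deep_bout.series
        peaks, relaxed = pm.to_peak_table(truth, atp_ref=7.22)
        series, ck = pm.build_series(peaks, relaxed, atp_ref=7.22,
                                     adp_rest=float(truth["adp"].iloc[0]))
        for col in ("pcr", "pi", "atp", "ph"):
            np.testing.assert_allclose(series[col], truth[col], rtol=1e-8,
                                       err_msg=col)
        np.testing.assert_allclose(series["adp"], truth["adp"], rtol=1e-6)
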
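"""Preprocessing tests: filtering, alignment, phase extraction, IQR fences,
R-peak detection, cardiac phase, RMSSD."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import respact as ra
from respact.preprocess import _iqr_fence

FS = 200.0


def _tone(freq, duration=120.0, fs=FS):
    t = np.arange(0, duration, 1 / fs)
    return ra.SignalTrace(np.sin(2 * np.pi * freq * t), fs, f"tone{freq}")


class TestBandpass:
    def test_in_band_tone_preserved(self):
        out = ra.bandpass(_tone(0.25), 0.1, 3.0)
        mid = slice(4000, -4000)  # avoid filter edges
        assert abs(np.abs(out.values[mid]).max() - 1.0) < 0.05

    def test_out_of_band_drift_attenuated(self):
        out = ra.bandpass(_tone(0.01, duration=600), 0.1, 3.0)
        mid = slice(20000, -20000)
        assert np.abs(out.values[mid]).max() < 0.1  # >= 90 % attenuation

    def test_dc_rejected(self):
        tr = ra.SignalTrace(np.full(int(60 * FS), 3.0), FS, "dc")
        out = ra.bandpass(tr, 0.1, 3.0)
        assert np.abs(out.values).max() < 1e-6

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ra.ConfigError):
            ra.bandpass(_tone(0.25), 0.1, 150.0)
        with pytest.raises(ra.ConfigError):
            ra.bandpass(_tone(0.25), 3.0, 0.1)


class TestAlignAirflow:
    def _belt(self, duration=120.0):
        t = np.arange(0, duration, 1 / FS)
        return ra.SignalTrace(-np.cos(2 * np.pi * t / 4), FS, "belt")

    def test_recovers_constructed_77_sample_delay(self):
        belt = self._belt()
        d = 77
        vals = -np.concatenate([np.full(d, belt.values[0]), belt.values[:-d]])
        airflow = ra.SignalTrace(vals, FS, "airflow")
        aligned, res = ra.align_airflow(airflow, belt)
        assert abs(res.lag - 0.385) <= 1 / FS + 1e-9
        assert res.max_corr >= 0.999

    def test_zero_delay_identity(self):
        belt = self._belt()
        airflow = ra.SignalTrace(-belt.values, FS, "airflow")
        aligned, res = ra.align_airflow(airflow, belt)
        assert res.lag == 0.0
        assert res.max_corr > 1 - 1e-9

    def test_recovers_simulator_delay_with_noise(self, noisy_recording):
        cfg = noisy_recording["config"]
        lag = noisy_recording["alignment"].lag
        assert abs(lag - cfg.airflow_delay) <= 1 / cfg.fs + 1e-9

    def test_constant_input_raises(self):
        belt = self._belt()
        flat = ra.SignalTrace(np.zeros(belt.n), FS, "flat")
        with pytest.raises(ra.AlignmentError):
            ra.align_airflow(flat, belt)


class TestRespPhase:
    def test_trough_sample_phase_near_zero(self, clean_recording):
        series = clean_recording["series"]
        cycles = clean_recording["cycles"]
        idx = np.rint(cycles["trough_time"].to_numpy() * series.fs).astype(int)
        ph = series.phase[idx[1:-1]]
        err = np.abs(np.angle(np.exp(1j * ph)))
        assert np.all(err < 0.2)

    def test_classification_agreement_clean(self, clean_recording):
        truth, series = clean_recording["truth"], clean_recording["series"]
        tp, est = truth.true_phase, series.phase
        ok = series.valid & np.isfinite(tp)
        extrema = np.zeros(tp.size, bool)
        marks = np.concatenate([
            np.where(np.abs(np.diff(tp)) > np.pi)[0],
            np.where(np.diff((tp >= np.pi).astype(int)) != 0)[0],
        ])
        for d in range(-2, 3):
            extrema[np.clip(marks + d, 0, tp.size - 1)] = True
        m = ok & ~extrema
        agreement = np.mean((tp[m] >= np.pi) == (est[m] >= np.pi))
        assert agreement >= 0.95

    def test_pure_cosine_cycle_durations(self):
        t = np.arange(0, 60, 1 / FS)
        series, cycles = ra.extract_resp_phase(
            ra.SignalTrace(np.cos(2 * np.pi * t / 4), FS, "cos")
        )
        assert np.all(np.abs(cycles["t_total"].to_numpy() - 4.0) <= 1 / FS + 1e-9)

    def test_unwrapped_phase_monotone(self, clean_recording):
        series = clean_recording["series"]
        ph = series.phase[series.valid]
        d = np.diff(ph)
        d[d < -np.pi] += 2 * np.pi  # unwrap at cycle boundaries
        assert np.all(d >= -1e-9)

    def test_too_few_cycles_raises(self):
        t = np.arange(0, 6, 1 / FS)
        with pytest.raises(ra.InsufficientDataError):
            ra.extract_resp_phase(ra.SignalTrace(np.cos(2 * np.pi * t / 4), FS, "c"))

    def test_exhale_proportion_round_trip(self, clean_recording):
        cycles, truth = clean_recording["cycles"], clean_recording["truth"]
        est = ra.baseline_exhalation_ratio(cycles)
        ct = truth.cycle_table
        realized = ct["t_ex"].sum() / ct["t_total"].sum()
        assert abs(est - realized) < 0.01


class TestCycleOutliers:
    def _table(self, totals, t_in=None):
        totals = np.asarray(totals, dtype=float)
        t_in = np.asarray(t_in, dtype=float) if t_in is not None else totals * 0.45
        trough = np.concatenate([[0], np.cumsum(totals)[:-1]])
        return pd.DataFrame({
            "trough_time": trough, "peak_time": trough + t_in,
            "next_trough_time": trough + totals, "t_in": t_in,
            "t_ex": totals - t_in, "t_total": totals,
            "excluded": False, "exclusion_reason": "none",
        })

    def test_degenerate_iqr_excludes_single_outlier(self):
        cycles = self._table([4, 4, 4, 4, 4, 4, 4, 20])
        out = ra.exclude_cycle_outliers(cycles)
        assert out["excluded"].tolist() == [False] * 7 + [True]
        assert out["exclusion_reason"].iloc[-1] != "none"

    def test_identical_durations_no_exclusions(self):
        out = ra.exclude_cycle_outliers(self._table([4] * 10))
        assert not out["excluded"].any()

    def test_idempotent(self):
        cycles = self._table([4, 4, 4, 4.2, 4, 4, 3.9, 4, 20, 4])
        once = ra.exclude_cycle_outliers(cycles)
        twice = ra.exclude_cycle_outliers(once)
        pd.testing.assert_frame_equal(once, twice)

    def test_injected_outlier_recall(self):
        cfg = ra.SimConfig(seed=21, duration=900, outlier_cycle_prob=0.05)
        _, _, truth = ra.simulate_respiration(cfg)
        from respact.synth import cycle_table_for_preprocessing
        cycles = ra.exclude_cycle_outliers(cycle_table_for_preprocessing(truth))
        injected = truth.cycle_table["is_outlier"].to_numpy()
        assert injected.sum() >= 3
        recall = cycles.loc[injected, "excluded"].mean()
        assert recall >= 0.9

    def test_small_n_raises(self):
        with pytest.raises(ra.InsufficientDataError):
            ra.exclude_cycle_outliers(self._table([4] * 5))


class TestCardiac:
    def test_detection_on_synthetic_ecg(self):
        cfg = ra.SimConfig(seed=22, duration=300, rr_sd=0.05)
        ecg, rpeaks = ra.simulate_cardiac(cfg)
        det = ra.detect_r_peaks(ra.bandpass(ecg, 0.5, 40.0)).rpeak_times
        tol = 0.05
        hits = np.array([np.min(np.abs(det - t)) <= tol for t in rpeaks])
        prec = np.array([np.min(np.abs(rpeaks - t)) <= tol for t in det])
        assert hits.mean() >= 0.99
        assert prec.mean() >= 0.99

    def test_noise_free_template_train_exact(self):
        cfg = ra.SimConfig(seed=23, duration=60, rr_sd=0.0, ecg_noise_sd=0.0)
        ecg, rpeaks = ra.simulate_cardiac(cfg)
        det = ra.detect_r_peaks(ecg).rpeak_times
        assert len(det) == len(rpeaks)
        assert np.all(np.abs(det - rpeaks) <= 1 / cfg.fs + 1e-9)

    def test_degenerate_trace_raises(self):
        with pytest.raises(ra.DetectionError):
            ra.detect_r_peaks(ra.SignalTrace(np.zeros(int(60 * FS)), FS, "flat"))

    def test_rr_outlier_example(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.concatenate([[0], np.cumsum([0.8] * 9 + [2.0])]))
        out = ra.exclude_rr_outliers(cc)
        assert out.excluded.tolist() == [False] * 9 + [True]

    def test_rr_all_equal_none_excluded(self):
        cc = ra.CardiacCycleTable(
            rpeak_times=np.arange(10) * 0.8, rr=np.full(9, 0.8)
        )
        assert not ra.exclude_rr_outliers(cc).excluded.any()

    def test_rr_infinite_k_no_exclusions(self):
        rng = np.random.default_rng(0)
        cc = ra.CardiacCycleTable(rpeak_times=np.cumsum(rng.uniform(0.3, 2.0, 30)))
        assert not ra.exclude_rr_outliers(cc, k=np.inf).excluded.any()

    @pytest.mark.parametrize(
        "offset,expected",
        [(0.0, 0.0), (0.4, np.pi), (0.3, 2 * np.pi * 0.375)],
    )
    def test_cardiac_phase_formula(self, offset, expected):
        cc = ra.CardiacCycleTable(rpeak_times=np.arange(0, 8, 0.8))
        ph, ok = ra.extract_cardiac_phase(cc, np.array([1.6 + offset]))
        assert ok[0]
        assert ph[0] == pytest.approx(expected, abs=1e-9)

    def test_cardiac_phase_outside_span_invalid(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.array([1.0, 1.8, 2.6]))
        ph, ok = ra.extract_cardiac_phase(cc, np.array([0.5, 3.0]))
        assert not ok.any()

    def test_cardiac_phase_continuity_at_peaks(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.array([0.0, 0.8, 1.7, 2.5]))
        eps = 1e-6
        ph_before, _ = ra.extract_cardiac_phase(cc, np.array([0.8 - eps]))
        ph_at, _ = ra.extract_cardiac_phase(cc, np.array([0.8]))
        assert ph_before[0] == pytest.approx(2 * np.pi, abs=1e-4)
        assert ph_at[0] == pytest.approx(0.0, abs=1e-12)


class TestRmssd:
    def test_hand_computed_values(self):
        assert ra.compute_rmssd([0.8, 0.8, 0.8]) == 0.0
        assert ra.compute_rmssd([0.8, 1.0, 0.8]) == pytest.approx(0.2, abs=1e-12)

    @given(st.floats(0.1, 5), st.floats(0.1, 5), st.integers(2, 20))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_alternating_closed_form(self, a, b, reps):
        seq = np.tile([a, b], reps)
        assert ra.compute_rmssd(seq) == pytest.approx(abs(a - b), rel=1e-9)

    def test_insufficient_data(self):
        with pytest.raises(ra.InsufficientDataError):
            ra.compute_rmssd([0.8])


def test_iqr_fence_uses_linear_interpolation():
    lo, hi = _iqr_fence(np.array([1.0, 2.0, 3.0, 4.0]), 1.0)
    # HF7: Q1 = 1.75, Q3 = 3.25, IQR = 1.5
    assert lo == pytest.approx(0.25)
    assert hi == pytest.approx(4.75)
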
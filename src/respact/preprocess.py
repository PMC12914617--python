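"""Physiological preprocessing: filters, airflow alignment, respiratory and
cardiac phase extraction, and IQR-based cycle/interval outlier fencing.

The respiratory phase convention throughout the package: troughs of the
(belt-aligned) respiration signal are phase 0 (and 2*pi), peaks are pi, so
inhalation occupies [0, pi) and exhalation [pi, 2*pi).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    AlignmentError,
    ConfigError,
    DetectionError,
    InsufficientDataError,
)

# Column order for respiratory cycle tables.
CYCLE_COLUMNS = [
    "trough_time",
    "peak_time",
    "next_trough_time",
    "t_in",
    "t_ex",
    "t_total",
    "excluded",
    "exclusion_reason",
]


@dataclass
class SignalTrace:
    """A regularly sampled channel.

    Parameters
    ----------
    values : array of float
        Sample values.
    fs : float
        Sampling rate in samples/second (the recordings modelled here use
        200 Hz).
    label : str
        Channel name (``"belt"``, ``"airflow"``, ``"ecg"``, ``"joystick"``).
    t0 : float
        Time of the first sample in seconds.
    """

    values: np.ndarray
    fs: float
    label: str = ""
    t0: float = 0.0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.fs <= 0:
            raise ConfigError("sampling rate must be positive")
        if self.values.ndim != 1:
            raise ConfigError("trace values must be one-dimensional")
        if not np.all(np.isfinite(self.values)):
            raise ConfigError(f"trace '{self.label}' contains non-finite values")

    @property
    def n(self) -> int:
        return self.values.size

    @property
    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.n) / self.fs

    @property
    def duration(self) -> float:
        return self.n / self.fs


@dataclass
class RespPhaseSeries:
    """Per-sample instantaneous respiratory phase.

    ``phase`` is in [0, 2*pi); ``valid`` is False outside complete cycles and
    inside cycles flagged by the outlier fence; ``cycle_index`` is -1 outside
    complete cycles.
    """

    phase: np.ndarray
    valid: np.ndarray
    cycle_index: np.ndarray
    fs: float
    t0: float = 0.0

    def lookup(self, times: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Nearest-sample phase at arbitrary times.

        Returns (phase, valid); queries outside the sampled span are invalid.
        """
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.rint((times - self.t0) * self.fs).astype(int)
        inside = (idx >= 0) & (idx < self.phase.size)
        idx_c = np.clip(idx, 0, self.phase.size - 1)
        phase = self.phase[idx_c]
        valid = inside & self.valid[idx_c]
        return phase, valid

    @property
    def span(self) -> tuple[float, float]:
        return self.t0, self.t0 + self.phase.size / self.fs


@dataclass
class CardiacCycleTable:
    """Detected R-peaks with RR intervals and exclusion flags.

    ``rr[i]`` is the interval from ``rpeak_times[i]`` to ``rpeak_times[i+1]``;
    ``excluded[i]`` marks intervals outside the IQR fence.
    """

    rpeak_times: np.ndarray
    rr: np.ndarray = field(default=None)
    excluded: np.ndarray = field(default=None)

    def __post_init__(self):
        self.rpeak_times = np.asarray(self.rpeak_times, dtype=float)
        if self.rr is None:
            self.rr = np.diff(self.rpeak_times)
        self.rr = np.asarray(self.rr, dtype=float)
        if np.any(self.rr <= 0):
            raise ConfigError("RR intervals must be strictly positive")
        if self.excluded is None:
            self.excluded = np.zeros(self.rr.size, dtype=bool)
        self.excluded = np.asarray(self.excluded, dtype=bool)


@dataclass(frozen=True)
class AlignmentResult:
    """Outcome of belt/airflow cross-correlation alignment."""

    lag: float       # seconds the airflow was advanced (thermal delay)
    max_corr: float  # Pearson r between belt and the aligned, inverted airflow


# ---------------------------------------------------------------------------
# Filtering and alignment
# ---------------------------------------------------------------------------

def bandpass(trace: SignalTrace, low_hz: float, high_hz: float) -> SignalTrace:
    """Zero-phase 4th-order Butterworth band-pass.

    The respiration band is (0.1, 3) Hz and the ECG band (0.5, 40) Hz.
    Applied forward-backward (``sosfiltfilt``) so phase is preserved, which
    matters because instantaneous phase is the analysis target.
    """
    nyq = trace.fs / 2.0
    if not (0 < low_hz < high_hz < nyq):
        raise ConfigError(
            f"band ({low_hz}, {high_hz}) Hz must satisfy 0 < low < high < "
            f"Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(4, [low_hz, high_hz], btype="bandpass", fs=trace.fs, output="sos")
    out = sps.sosfiltfilt(sos, trace.values)
    return SignalTrace(out, trace.fs, label=trace.label, t0=trace.t0)


def align_airflow(
    airflow: SignalTrace, belt: SignalTrace, max_lag: float = 2.0
) -> tuple[SignalTrace, AlignmentResult]:
    """Invert the thermal airflow channel and align it to the belt.

    The thermal transducer responds with a positive, sub-second delay and
    opposite sign relative to the belt. The airflow is sign-inverted and the
    integer-sample lag in [0, max_lag] maximizing the Pearson correlation
    with the belt is found; the output is the inverted airflow advanced by
    that lag (end padded with its last value to keep the length).
    """
    if airflow.fs != belt.fs:
        raise ConfigError("airflow and belt must share a sampling rate")
    n = min(airflow.n, belt.n)
    if max_lag >= (n / airflow.fs) / 4:
        raise ConfigError("max_lag must be below a quarter of the overlap span")
    inv = -airflow.values[:n]
    b = belt.values[:n]
    if np.std(inv) == 0 or np.std(b) == 0:
        raise AlignmentError("alignment undefined for a constant channel")

    max_shift = int(round(max_lag * airflow.fs))
    best_lag, best_r = 0, -np.inf
    for lag in range(max_shift + 1):
        x = b[: n - lag] if lag else b
        y = inv[lag:]
        sx, sy = np.std(x), np.std(y)
        if sx == 0 or sy == 0:
            continue
        r = np.mean((x - x.mean()) * (y - y.mean())) / (sx * sy)
        if r > best_r:
            best_r, best_lag = r, lag

    aligned = np.concatenate([inv[best_lag:], np.full(best_lag, inv[-1])])
    out = SignalTrace(aligned, airflow.fs, label="airflow_aligned", t0=airflow.t0)
    return out, AlignmentResult(lag=best_lag / airflow.fs, max_corr=float(best_r))


# ---------------------------------------------------------------------------
# Respiratory phase and cycle segmentation
# ---------------------------------------------------------------------------

def extract_resp_phase(
    aligned_airflow: SignalTrace,
) -> tuple[RespPhaseSeries, pd.DataFrame]:
    """Instantaneous respiratory phase from the analytic signal.

    The Hilbert-transform angle of the *negated* aligned airflow segments
    the record into breath cycles (phase wraps = approximate troughs; the
    aligned airflow is belt-like, so its troughs are ends of exhalation).
    Because real breath cycles are asymmetric (exhalation outlasts
    inhalation), the raw analytic angle drifts systematically around the
    extrema, so the phase is then anchored to the refined waveform extrema:
    troughs map to 0/2*pi, peaks to pi, linear in time within each half-
    cycle. Inhalation is [0, pi), exhalation [pi, 2*pi); samples outside
    complete cycles are invalid.
    """
    x = aligned_airflow.values
    y = x - x.mean()  # belt-like after alignment: trough = end of exhalation
    # angle of the negated signal puts phase 0 at waveform troughs
    phase_h = np.mod(np.angle(sps.hilbert(-y)), 2 * np.pi)
    fs, t0 = aligned_airflow.fs, aligned_airflow.t0

    wraps = np.where(np.diff(phase_h) < -np.pi)[0] + 1  # approximate troughs
    if wraps.size < 4:
        raise InsufficientDataError(
            f"need at least 3 complete respiratory cycles, found {max(wraps.size - 1, 0)}"
        )
    # refine each trough to the local waveform minimum
    half = max(1, int(round(0.35 * fs)))
    troughs = []
    for w in wraps:
        a, b = max(0, w - half), min(y.size, w + half + 1)
        troughs.append(a + int(np.argmin(y[a:b])))
    troughs = np.unique(troughs)
    troughs = troughs[np.concatenate([[True], np.diff(troughs) > int(0.5 * fs)])]
    if troughs.size < 4:
        raise InsufficientDataError("need at least 3 complete respiratory cycles")

    phase = phase_h.copy()  # outside complete cycles keep the raw angle (invalid anyway)
    cycle_index = np.full(x.size, -1, dtype=int)
    rows = []
    for i in range(troughs.size - 1):
        a, b = troughs[i], troughs[i + 1]
        peak = a + int(np.argmax(y[a:b]))
        if peak <= a or peak >= b - 1:
            peak = (a + b) // 2  # degenerate segment; keep the cycle usable
        s = np.arange(a, b)
        phase[a:b] = np.where(
            s < peak,
            np.pi * (s - a) / (peak - a),
            np.pi + np.pi * (s - peak) / (b - peak),
        )
        cycle_index[a:b] = i
        rows.append(
            {
                "trough_time": t0 + a / fs,
                "peak_time": t0 + peak / fs,
                "next_trough_time": t0 + b / fs,
                "t_in": (peak - a) / fs,
                "t_ex": (b - peak) / fs,
                "t_total": (b - a) / fs,
                "excluded": False,
                "exclusion_reason": "none",
            }
        )

    cycles = pd.DataFrame(rows, columns=CYCLE_COLUMNS)
    valid = cycle_index >= 0
    series = RespPhaseSeries(phase=phase, valid=valid, cycle_index=cycle_index, fs=fs, t0=t0)
    return series, cycles


def _iqr_fence(values: np.ndarray, k: float) -> tuple[float, float]:
    # Hyndman-Fan definition 7 (numpy's default linear interpolation)
    q1, q3 = np.percentile(values, [25, 75])
    iqr = q3 - q1
    return q1 - k * iqr, q3 + k * iqr


def exclude_cycle_outliers(cycles: pd.DataFrame, k: float = 2.5) -> pd.DataFrame:
    """Flag respiratory cycles whose total, inhale, or exhale duration falls
    outside [Q1 - k*IQR, Q3 + k*IQR], each fence computed over the
    participant's own cycles. Flags are set, nothing is deleted; re-running
    on flagged output is a no-op because fences use all cycles.
    """
    if len(cycles) < 8:
        raise InsufficientDataError("need at least 8 cycles for IQR fencing")
    out = cycles.copy()
    reasons = np.array(["none"] * len(out), dtype=object)
    excluded = np.zeros(len(out), dtype=bool)
    # priority of reported reason: total, then inhale, then exhale
    for col, reason in (("t_ex", "exhale_outlier"), ("t_in", "inhale_outlier"), ("t_total", "total_outlier")):
        lo, hi = _iqr_fence(out[col].to_numpy(), k)
        bad = (out[col].to_numpy() < lo) | (out[col].to_numpy() > hi)
        reasons[bad] = reason
        excluded |= bad
    out["excluded"] = excluded
    out["exclusion_reason"] = reasons
    return out


def apply_cycle_exclusions(series: RespPhaseSeries, cycles: pd.DataFrame) -> RespPhaseSeries:
    """Propagate cycle exclusion flags into the per-sample validity mask."""
    excluded_ix = set(np.flatnonzero(cycles["excluded"].to_numpy()))
    valid = (series.cycle_index >= 0) & ~np.isin(
        series.cycle_index, np.fromiter(excluded_ix, dtype=int, count=len(excluded_ix))
    )
    return replace(series, valid=valid)


# ---------------------------------------------------------------------------
# Cardiac preprocessing
# ---------------------------------------------------------------------------

def detect_r_peaks(ecg: SignalTrace) -> CardiacCycleTable:
    """R-peak detection by a Pan-Tompkins-style transform.

    Derivative -> squaring -> 150 ms moving-average integration, candidate
    peaks above an adaptive amplitude threshold with a 250 ms refractory
    period, each refined to the local ECG maximum within +/-80 ms.
    """
    x = ecg.values
    if x.size < int(ecg.fs) or np.std(x) == 0:
        raise DetectionError("ECG trace too short or degenerate for R-peak detection")
    deriv = np.gradient(x)
    sq = deriv ** 2
    win = max(1, int(round(0.150 * ecg.fs)))
    integ = np.convolve(sq, np.ones(win) / win, mode="same")

    thr = 0.3 * np.quantile(integ, 0.99)
    cand, _ = sps.find_peaks(integ, height=thr, distance=int(round(0.250 * ecg.fs)))
    if cand.size == 0:
        raise DetectionError("no R-peaks found")

    half = int(round(0.080 * ecg.fs))
    peaks = []
    for c in cand:
        a, b = max(0, c - half), min(x.size, c + half + 1)
        peaks.append(a + int(np.argmax(x[a:b])))
    peaks = np.unique(peaks)
    # unique() can merge refined candidates; enforce the refractory period
    keep = [peaks[0]]
    for p in peaks[1:]:
        if p - keep[-1] >= int(round(0.250 * ecg.fs)):
            keep.append(p)
    times = ecg.t0 + np.asarray(keep) / ecg.fs
    if times.size < 2:
        raise DetectionError("fewer than two R-peaks found")
    return CardiacCycleTable(rpeak_times=times)


def exclude_rr_outliers(cycles: CardiacCycleTable, k: float = 2.0) -> CardiacCycleTable:
    """Flag RR intervals outside [Q1 - k*IQR, Q3 + k*IQR] (k = 2.0 default)."""
    if cycles.rr.size < 8:
        raise InsufficientDataError("need at least 8 RR intervals for IQR fencing")
    if np.isinf(k):
        excluded = np.zeros(cycles.rr.size, dtype=bool)
    else:
        lo, hi = _iqr_fence(cycles.rr, k)
        excluded = (cycles.rr < lo) | (cycles.rr > hi)
    return CardiacCycleTable(
        rpeak_times=cycles.rpeak_times.copy(), rr=cycles.rr.copy(), excluded=excluded
    )


def extract_cardiac_phase(
    cycles: CardiacCycleTable, query_times: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Cardiac phase 2*pi*(t - R_prev)/(R_next - R_prev) at query times.

    Queries outside the first/last peak span or inside excluded RR intervals
    get an invalid flag (phase NaN), never an exception.
    """
    t = np.atleast_1d(np.asarray(query_times, dtype=float))
    peaks = cycles.rpeak_times
    idx = np.searchsorted(peaks, t, side="right") - 1
    inside = (idx >= 0) & (idx < cycles.rr.size)
    idx_c = np.clip(idx, 0, cycles.rr.size - 1)
    phase = 2 * np.pi * (t - peaks[idx_c]) / cycles.rr[idx_c]
    valid = inside & ~cycles.excluded[idx_c]
    phase = np.where(valid, np.mod(phase, 2 * np.pi), np.nan)
    return phase, valid


def compute_rmssd(intervals: np.ndarray) -> float:
    """Root mean square of successive differences of an interval series."""
    x = np.asarray(intervals, dtype=float)
    if x.size < 2:
        raise InsufficientDataError("RMSSD needs at least 2 intervals")
    return float(np.sqrt(np.mean(np.diff(x) ** 2)))
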
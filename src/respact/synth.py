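"""Ground-truthed cardiorespiratory and behavioral simulation.

The generator emulates the recording setup the analysis expects: a
respiration belt and a delayed, sign-inverted thermal airflow channel at
200 Hz, an ECG with detectable R-peaks, a Libet clock session (rotating dot,
self-chosen key press/release, 4-8 s inter-trial intervals) and a self-paced
elbow flexion/extension session (joystick push/pull every 8-12 s). Breath
cycles are asymmetric (inhalation ~1.78 s, exhalation ~2.17 s) so that
uniform-in-time events are biased toward exhalation -- the bias the
surrogate-based inference must correct.

Event/phase coupling is controllable: ``uniform_time`` places actions purely
by waiting times, ``uniform_phase`` and ``von_mises`` relocate each action to
the first moment (after its minimum wait) at which the true respiratory
phase crosses a drawn target angle; kappa = 0 recovers phase-uniform
behavior and large kappa concentrates actions at ``mu``.

Every output comes with exact ground truth (per-sample phase, cycle table,
per-event phase, R-peak times, injected anomaly flags) so preprocessing and
inference can be scored against known answers.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import CapacityError, ConfigError
from .preprocess import CYCLE_COLUMNS, SignalTrace

TWO_PI = 2 * np.pi

# substream tags so each simulated subsystem has an independent, reproducible
# generator derived from the single config seed
_STREAM_RESP = 1
_STREAM_CARDIAC = 2
_STREAM_AIRFLOW_NOISE = 3
_STREAM_ECG_NOISE = 4
_STREAM_SESSION = {"key_press": 5, "key_release": 6, "pull": 7, "push": 8}

EVENT_COLUMNS = ["time_s", "task", "condition", "event_type", "trial_index"]


@dataclass(frozen=True)
class SimConfig:
    """Simulation parameters; defaults are group-average adult resting
    physiology (inhale 1.781 s, exhale 2.173 s, RR 0.800 s, thermal airflow
    delay 382.5 ms, 200 Hz sampling)."""

    seed: int = 0
    duration: float = 600.0
    fs: float = 200.0
    inhale_mean: float = 1.781
    inhale_sd: float = 0.422
    exhale_mean: float = 2.173
    exhale_sd: float = 0.603
    airflow_delay: float = 0.3825
    airflow_noise_sd: float = 0.05
    rr_mean: float = 0.800
    rr_sd: float = 0.100
    rr_ar: float = 0.4          # AR(1) coefficient of the RR series
    ecg_noise_sd: float = 0.02
    coupling_mode: str = "uniform_time"   # uniform_time | uniform_phase | von_mises
    mu: float = 0.0             # target phase, radians in [0, 2*pi)
    kappa: float = 0.0          # von Mises concentration, >= 0
    pause_prob: float = 0.0     # per-cycle probability of an end-expiratory pause
    pause_mean: float = 1.0     # mean of the Exponential pause duration, s
    outlier_cycle_prob: float = 0.0  # per-cycle probability of an abnormally long cycle
    outlier_scale: float = 4.0  # duration multiplier for injected outlier cycles
    wait_log_median: float = 4.0     # median of the lognormal Libet waiting time, s
    wait_log_sigma: float = 0.35     # log-scale sd of the waiting time
    press_rt_mean: float = 0.414     # key-release condition: initial press RT, s
    press_rt_sd: float = 0.105

    def __post_init__(self):
        if self.duration <= 0 or self.fs <= 0:
            raise ConfigError("duration and fs must be strictly positive")
        for name in ("inhale_mean", "exhale_mean", "rr_mean", "outlier_scale",
                     "pause_mean", "wait_log_median"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be strictly positive")
        for name in ("inhale_sd", "exhale_sd", "rr_sd", "airflow_noise_sd",
                     "ecg_noise_sd", "airflow_delay", "kappa"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be nonnegative")
        if not (0 <= self.mu < TWO_PI):
            raise ConfigError("mu must lie in [0, 2*pi)")
        if self.rr_sd >= self.rr_mean:
            raise ConfigError("rr_sd must be smaller than rr_mean")
        if not (0 <= self.pause_prob <= 1 and 0 <= self.outlier_cycle_prob <= 1):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.coupling_mode not in ("uniform_time", "uniform_phase", "von_mises"):
            raise ConfigError(f"unknown coupling_mode '{self.coupling_mode}'")
        if not (-1 < self.rr_ar < 1):
            raise ConfigError("rr_ar must lie in (-1, 1)")

    def rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), int(stream)])


@dataclass
class GroundTruth:
    """Exact simulation ground truth.

    ``cycle_table`` carries trough/peak/next-trough times, durations and the
    injected pause/outlier flags; ``true_phase`` is the per-sample phase
    (piecewise linear, 0 -> pi over inhalation, pi -> 2*pi over exhalation;
    None when only the analytic cycle table was generated);
    ``event_true_phase`` and ``rpeak_times`` are filled by the session and
    cardiac simulators.
    """

    cycle_table: pd.DataFrame
    fs: float
    true_phase: np.ndarray | None = None
    event_true_phase: np.ndarray | None = None
    rpeak_times: np.ndarray | None = None

    # -- analytic phase geometry -------------------------------------------
    @property
    def span(self) -> tuple[float, float]:
        ct = self.cycle_table
        return float(ct["trough_time"].iloc[0]), float(ct["next_trough_time"].iloc[-1])

    def phase_at(self, times) -> np.ndarray:
        """True phase at arbitrary times (NaN outside the generated cycles)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        ct = self.cycle_table
        troughs = ct["trough_time"].to_numpy()
        peaks = ct["peak_time"].to_numpy()
        nexts = ct["next_trough_time"].to_numpy()
        idx = np.searchsorted(troughs, t, side="right") - 1
        ok = (idx >= 0) & (t < nexts[np.clip(idx, 0, len(ct) - 1)])
        i = np.clip(idx, 0, len(ct) - 1)
        inhale = t < peaks[i]
        t_in = peaks[i] - troughs[i]
        t_ex = nexts[i] - peaks[i]
        ph = np.where(
            inhale,
            np.pi * (t - troughs[i]) / t_in,
            np.pi + np.pi * (t - peaks[i]) / t_ex,
        )
        ph = np.mod(ph, TWO_PI)
        return np.where(ok, ph, np.nan)

    def time_of_phase(self, target: float, t_min: float) -> float | None:
        """First time >= t_min at which the true phase equals ``target``.

        Solved exactly on the piecewise-linear phase; returns None when the
        crossing falls beyond the last generated cycle.
        """
        target = float(np.mod(target, TWO_PI))
        ct = self.cycle_table
        troughs = ct["trough_time"].to_numpy()
        peaks = ct["peak_time"].to_numpy()
        nexts = ct["next_trough_time"].to_numpy()
        i = int(np.searchsorted(troughs, t_min, side="right") - 1)
        i = max(i, 0)
        while i < len(ct):
            if target < np.pi:
                t = troughs[i] + (target / np.pi) * (peaks[i] - troughs[i])
            else:
                t = peaks[i] + ((target - np.pi) / np.pi) * (nexts[i] - peaks[i])
            if t >= t_min:
                return float(t)
            i += 1
        return None


# ---------------------------------------------------------------------------
# Respiration
# ---------------------------------------------------------------------------

def _draw_durations(rng: np.random.Generator, mean: float, sd: float, n: int) -> np.ndarray:
    """Positive-support draws with the requested mean/SD (Gamma; degenerate
    at ``mean`` when sd = 0)."""
    if sd == 0:
        return np.full(n, mean)
    shape = (mean / sd) ** 2
    scale = sd ** 2 / mean
    return rng.gamma(shape, scale, size=n)


def simulate_resp_cycles(config: SimConfig) -> pd.DataFrame:
    """Draw breath cycles covering the configured duration (plus one extra
    so every sample lies inside a complete cycle).

    Returns the ground-truth cycle table with ``is_pause``/``is_outlier``
    flags; an inserted end-expiratory pause extends the exhale (waveform held
    at the trough), an outlier cycle is the drawn cycle scaled by
    ``outlier_scale``.
    """
    rng = config.rng(_STREAM_RESP)
    n_guess = int(np.ceil(config.duration / max(config.inhale_mean + config.exhale_mean, 0.2))) + 8
    rows, t = [], 0.0
    while t <= config.duration:
        t_in = _draw_durations(rng, config.inhale_mean, config.inhale_sd, n_guess)
        t_ex = _draw_durations(rng, config.exhale_mean, config.exhale_sd, n_guess)
        is_out = rng.random(n_guess) < config.outlier_cycle_prob
        is_pause = rng.random(n_guess) < config.pause_prob
        pause = np.where(is_pause, rng.exponential(config.pause_mean, n_guess), 0.0)
        t_in = np.where(is_out, t_in * config.outlier_scale, t_in)
        t_ex = np.where(is_out, t_ex * config.outlier_scale, t_ex)
        for j in range(n_guess):
            trough = t
            peak = trough + t_in[j]
            nxt = peak + t_ex[j] + pause[j]
            rows.append(
                (trough, peak, nxt, t_in[j], t_ex[j] + pause[j], nxt - trough,
                 pause[j], bool(is_pause[j]), bool(is_out[j]))
            )
            t = nxt
            if t > config.duration:
                break
    return pd.DataFrame(
        rows,
        columns=[
            "trough_time", "peak_time", "next_trough_time",
            "t_in", "t_ex", "t_total", "pause_dur", "is_pause", "is_outlier",
        ],
    )


def simulate_respiration(config: SimConfig) -> tuple[SignalTrace, SignalTrace, GroundTruth]:
    """Belt + thermal airflow traces with exact ground truth.

    The belt is a chain of half-cosine segments (trough -1 to peak +1 over
    each inhale, back over each exhale, trough value held during pauses).
    The airflow channel is a waveshaped (tanh), sign-inverted copy of the
    belt delayed by ``airflow_delay`` plus white noise -- the waveshaping
    flattens the extrema (flow-sensor-like) while preserving their timing so
    the configured thermal delay is exactly recoverable.
    """
    if config.duration < 30:
        raise ConfigError("duration must be at least 30 s")
    cycles = simulate_resp_cycles(config)
    n = int(round(config.duration * config.fs))
    times = np.arange(n) / config.fs

    troughs = cycles["trough_time"].to_numpy()
    peaks = cycles["peak_time"].to_numpy()
    nexts = cycles["next_trough_time"].to_numpy()
    pauses = cycles["pause_dur"].to_numpy()

    idx = np.clip(np.searchsorted(troughs, times, side="right") - 1, 0, len(cycles) - 1)
    t_in = peaks[idx] - troughs[idx]
    ex_core = nexts[idx] - peaks[idx] - pauses[idx]
    in_seg = times < peaks[idx]
    tau_in = (times - troughs[idx]) / t_in
    tau_ex = np.clip((times - peaks[idx]) / ex_core, 0.0, 1.0)  # clipped -> hold at trough during pause
    belt_vals = np.where(in_seg, -np.cos(np.pi * tau_in), np.cos(np.pi * tau_ex))

    truth = GroundTruth(cycle_table=cycles, fs=config.fs)
    truth.true_phase = truth.phase_at(times)

    # half-up rounding so 0.3825 s at 200 Hz gives exactly 77 samples
    delay_samples = int(np.floor(config.airflow_delay * config.fs + 0.5))
    shaped = np.tanh(1.8 * belt_vals) / np.tanh(1.8)
    delayed = np.concatenate([np.full(delay_samples, shaped[0]), shaped[: n - delay_samples]])
    noise = config.rng(_STREAM_AIRFLOW_NOISE).normal(0.0, config.airflow_noise_sd, n)
    airflow_vals = -delayed + noise

    belt = SignalTrace(belt_vals, config.fs, label="belt")
    airflow = SignalTrace(airflow_vals, config.fs, label="airflow")
    return belt, airflow, truth


# ---------------------------------------------------------------------------
# Cardiac
# ---------------------------------------------------------------------------

def _qrs_template(fs: float) -> tuple[np.ndarray, int]:
    """Fixed QRS-T-like template; returns (waveform, index of the R sample)."""
    t = np.arange(-0.100, 0.351, 1.0 / fs)
    r = np.exp(-0.5 * (t / 0.010) ** 2)
    q = -0.15 * np.exp(-0.5 * ((t + 0.030) / 0.010) ** 2)
    s = -0.30 * np.exp(-0.5 * ((t - 0.030) / 0.010) ** 2)
    tw = 0.20 * np.exp(-0.5 * ((t - 0.250) / 0.040) ** 2)
    wave = r + q + s + tw
    return wave, int(np.argmin(np.abs(t)))


def simulate_cardiac(config: SimConfig) -> tuple[SignalTrace, np.ndarray]:
    """ECG trace (QRS-like template train plus noise) with ground-truth
    R-peak times; RR intervals follow a positive AR(1) Gaussian around
    ``rr_mean`` with marginal SD ``rr_sd``."""
    if config.duration < 30:
        raise ConfigError("duration must be at least 30 s")
    rng = config.rng(_STREAM_CARDIAC)
    n_beats = int(np.ceil(config.duration / max(config.rr_mean - 3 * config.rr_sd, 0.2))) + 4
    z = np.zeros(n_beats)
    eps = rng.normal(size=n_beats)
    a = config.rr_ar
    z[0] = eps[0]
    for i in range(1, n_beats):
        z[i] = a * z[i - 1] + np.sqrt(1 - a ** 2) * eps[i]
    rr = np.maximum(config.rr_mean + config.rr_sd * z, config.rr_mean / 4)
    rpeaks = 0.5 + np.concatenate([[0.0], np.cumsum(rr)])
    rpeaks = rpeaks[rpeaks < config.duration - 0.4]

    n = int(round(config.duration * config.fs))
    ecg = np.zeros(n)
    wave, r_idx = _qrs_template(config.fs)
    for tp in rpeaks:
        c = int(round(tp * config.fs))
        a0, b0 = c - r_idx, c - r_idx + wave.size
        wa, wb = max(0, -a0), wave.size - max(0, b0 - n)
        ecg[max(a0, 0): min(b0, n)] += wave[wa:wb]
    ecg += config.rng(_STREAM_ECG_NOISE).normal(0.0, config.ecg_noise_sd, n)
    return SignalTrace(ecg, config.fs, label="ecg"), rpeaks


# ---------------------------------------------------------------------------
# Behavioral sessions
# ---------------------------------------------------------------------------

MIN_WAIT = 2.560   # one full dot rotation, s
ITI_RANGE = (4.0, 8.0)
ELBOW_GAP_RANGE = (8.0, 12.0)
JOYSTICK_THRESHOLD = 0.40
_PULSE_WIDTH = 1.2  # s, raised-sine joystick excursion


def _coupled_action_time(
    config: SimConfig, truth: GroundTruth, rng: np.random.Generator, earliest: float
) -> float | None:
    """Action time under the configured coupling mode, never before ``earliest``."""
    if config.coupling_mode == "uniform_time":
        return earliest
    if config.coupling_mode == "uniform_phase":
        target = rng.uniform(0.0, TWO_PI)
    else:  # von_mises; kappa = 0 reduces to a uniform target phase
        target = np.mod(rng.vonmises(config.mu, config.kappa), TWO_PI)
    return truth.time_of_phase(target, earliest)


def simulate_libet_session(
    config: SimConfig, truth: GroundTruth, condition: str, n_trials: int
) -> pd.DataFrame:
    """Libet clock trials: dot onset, self-chosen key press (or initial press
    + self-chosen release), 4-8 s inter-trial intervals.

    The waiting time from onset to action is lognormal (median
    ``wait_log_median``) truncated below at one dot rotation (2.56 s); under
    phase coupling the action is relocated to the first later moment whose
    true phase equals the drawn von Mises target. Returns an event table with
    the exact per-event true phase.
    """
    if condition not in ("key_press", "key_release"):
        raise ConfigError(f"unknown Libet condition '{condition}'")
    rng = config.rng(_STREAM_SESSION[condition])
    t_lo, t_hi = truth.span
    rows = []
    t = t_lo + 2.0
    for trial in range(n_trials):
        onset = t
        rows.append((onset, "libet", condition, "dot_onset", trial))
        if condition == "key_release":
            rt = max(0.05, rng.normal(config.press_rt_mean, config.press_rt_sd))
            rows.append((onset + rt, "libet", condition, "key_press", trial))
        wait = max(MIN_WAIT, rng.lognormal(np.log(config.wait_log_median), config.wait_log_sigma))
        action = _coupled_action_time(config, truth, rng, onset + wait)
        if action is None or action > t_hi - 1.0:
            raise CapacityError(
                f"recording too short for {n_trials} Libet trials (failed at trial {trial})"
            )
        action_type = "key_press" if condition == "key_press" else "key_release"
        rows.append((action, "libet", condition, action_type, trial))
        t = action + rng.uniform(*ITI_RANGE)

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events["true_phase"] = truth.phase_at(events["time_s"].to_numpy())
    truth.event_true_phase = events.loc[
        events["event_type"] == action_type, "true_phase"
    ].to_numpy()
    return events


def simulate_elbow_session(
    config: SimConfig, truth: GroundTruth, condition: str, n_trials: int
) -> tuple[pd.DataFrame, SignalTrace]:
    """Self-paced joystick push/pull actions every 8-12 s plus the joystick
    position trace.

    Each action produces a smooth raised-sine pulse of signed unit amplitude
    timed so its |0.40| threshold crossing occurs at the action time; the
    first sample strictly beyond the threshold is recorded per action
    (``cross_sample`` column) so detector accuracy is exactly measurable.
    """
    if condition not in ("pull", "push"):
        raise ConfigError(f"unknown elbow condition '{condition}'")
    rng = config.rng(_STREAM_SESSION[condition])
    t_lo, t_hi = truth.span
    rows, t = [], t_lo + 5.0
    for trial in range(n_trials):
        gap = rng.uniform(*ELBOW_GAP_RANGE) if trial else 0.0
        action = _coupled_action_time(config, truth, rng, t + gap)
        if action is None or action > t_hi - _PULSE_WIDTH - 1.0:
            raise CapacityError(
                f"recording too short for {n_trials} elbow actions (failed at action {trial})"
            )
        rows.append((action, "elbow", condition, "action_onset", trial))
        t = action

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    events["true_phase"] = truth.phase_at(events["time_s"].to_numpy())
    truth.event_true_phase = events["true_phase"].to_numpy()

    n = int(round(config.duration * config.fs))
    joy = np.zeros(n)
    sign = 1.0 if condition == "push" else -1.0
    # threshold crossing of sin^2(pi*tau) occurs at tau_c; start each pulse
    # tau_c * width before the action so the crossing lands on the action time
    tau_c = np.arcsin(np.sqrt(JOYSTICK_THRESHOLD)) / np.pi
    cross_samples = np.full(len(events), -1, dtype=int)
    for i, ta in enumerate(events["time_s"].to_numpy()):
        start = ta - tau_c * _PULSE_WIDTH
        a = int(np.ceil(start * config.fs))
        b = min(n, int(np.floor((start + _PULSE_WIDTH) * config.fs)) + 1)
        tt = np.arange(a, b) / config.fs
        pulse = sign * np.sin(np.pi * (tt - start) / _PULSE_WIDTH) ** 2
        joy[a:b] += pulse
        over = np.flatnonzero(np.abs(joy[a:b]) > JOYSTICK_THRESHOLD)
        cross_samples[i] = a + over[0]
    events["cross_sample"] = cross_samples
    return events, SignalTrace(np.clip(joy, -1, 1), config.fs, label="joystick")


# ---------------------------------------------------------------------------
# Session writers
# ---------------------------------------------------------------------------

def write_session(
    outdir: str | Path,
    config: SimConfig,
    traces: dict[str, SignalTrace],
    events: pd.DataFrame,
    truth: GroundTruth | None = None,
) -> Path:
    """Write one simulated session: a time_s,value CSV per channel, an events
    CSV, a JSON sidecar with fs/seed/full config, and (when ground truth is
    given) a ground-truth cycle CSV plus event true phases."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, tr in traces.items():
        pd.DataFrame({"time_s": tr.times, "value": tr.values}).to_csv(
            outdir / f"{name}.csv", index=False
        )
    events.to_csv(outdir / "events.csv", index=False)
    sidecar = {"fs": config.fs, "seed": config.seed,
               "config": dataclasses.asdict(config), "channels": sorted(traces)}
    (outdir / "session.json").write_text(json.dumps(sidecar, indent=2))
    if truth is not None:
        truth.cycle_table.to_csv(outdir / "ground_truth_cycles.csv", index=False)
    return outdir


def cycle_table_for_preprocessing(truth: GroundTruth) -> pd.DataFrame:
    """Ground-truth cycle table in the preprocessing schema (for oracle use)."""
    ct = truth.cycle_table
    out = ct[["trough_time", "peak_time", "next_trough_time", "t_in", "t_ex", "t_total"]].copy()
    out["excluded"] = False
    out["exclusion_reason"] = "none"
    return out[CYCLE_COLUMNS]
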
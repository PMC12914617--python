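"""Behavioral event processing: joystick onset detection, trial validity
rules for the Libet and elbow tasks, participant inclusion, and attaching
respiratory/cardiac phases to events.

Boundary conventions (documented and tested): all exclusion rules use strict
inequalities, so an action at exactly 2.560 s after dot onset, an initial
press at exactly 1.000 s, and elbow intervals of exactly 5 s or 30 s are all
retained; a participant with exactly 20 valid trials per condition is
included.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigError
from .preprocess import CardiacCycleTable, RespPhaseSeries, SignalTrace, extract_cardiac_phase

MIN_LATENCY = 2.560     # s, one full dot rotation
MAX_PRESS_LATENCY = 1.0  # s, key-release condition initial press deadline
MIN_ITI = 5.0           # s, elbow inter-movement bounds
MAX_ITI = 30.0
MIN_VALID_TRIALS = 20   # Libet participant-inclusion threshold


def _ensure_validity_columns(events: pd.DataFrame) -> pd.DataFrame:
    out = events.copy()
    if "valid" not in out:
        out["valid"] = True
    if "exclusion_reason" not in out:
        out["exclusion_reason"] = "none"
    return out


def detect_joystick_onsets(
    trace: SignalTrace,
    direction: str,
    threshold: float = 0.40,
    refractory: float = 4.0,
) -> pd.DataFrame:
    """Threshold-crossing onset detection on the joystick position trace.

    An onset is the first sample with signed position strictly beyond
    +threshold (push) or -threshold (pull); crossings within the refractory
    window after a detection are suppressed. An empty result is allowed.
    """
    if direction not in ("push", "pull"):
        raise ConfigError(f"unknown direction '{direction}'")
    v = trace.values
    over = v > threshold if direction == "push" else v < -threshold
    idx = np.flatnonzero(over)
    gap = int(round(refractory * trace.fs))
    kept = []
    last = -gap - 1
    for i in idx:
        if i - last >= gap:
            kept.append(i)
            last = i
    return pd.DataFrame(
        {
            "time_s": trace.t0 + np.asarray(kept, dtype=float) / trace.fs,
            "sample": np.asarray(kept, dtype=int),
            "task": "elbow",
            "condition": direction,
            "event_type": "action_onset",
            "trial_index": np.arange(len(kept)),
            "valid": True,
            "exclusion_reason": "none",
        }
    )


def filter_libet_trials(events: pd.DataFrame, condition: str) -> pd.DataFrame:
    """Apply the Libet-task validity rules per trial.

    key_press: the trial is invalid when the action latency from dot onset is
    below one full rotation (2.560 s). key_release: invalid when the initial
    press comes more than 1 s after dot onset or the release latency is below
    2.560 s. Trials without a dot onset or without the expected action are
    flagged structurally invalid, never silently dropped.
    """
    if condition not in ("key_press", "key_release"):
        raise ConfigError(f"unknown Libet condition '{condition}'")
    out = _ensure_validity_columns(events)
    action_type = "key_press" if condition == "key_press" else "key_release"
    for trial, grp in out.groupby("trial_index"):
        onsets = grp[grp["event_type"] == "dot_onset"]
        actions = grp[grp["event_type"] == action_type]
        reason = None
        if len(onsets) != 1 or len(actions) != 1:
            reason = "structural_error"
        else:
            onset = float(onsets["time_s"].iloc[0])
            latency = float(actions["time_s"].iloc[0]) - onset
            if condition == "key_release":
                presses = grp[(grp["event_type"] == "key_press")]
                if len(presses) != 1:
                    reason = "structural_error"
                elif float(presses["time_s"].iloc[0]) - onset > MAX_PRESS_LATENCY:
                    reason = "late_initial_press"
            if reason is None and latency < MIN_LATENCY:
                reason = "premature_action"
        if reason is not None:
            out.loc[grp.index, "valid"] = False
            out.loc[grp.index, "exclusion_reason"] = reason
    return out


def filter_elbow_trials(
    events: pd.DataFrame,
    min_iti: float = MIN_ITI,
    max_iti: float = MAX_ITI,
    chain_to_retained: bool = True,
) -> pd.DataFrame:
    """Apply the elbow-task inter-movement interval rule.

    An action is invalid when its interval from the previous action is
    strictly below ``min_iti`` or strictly above ``max_iti``. The first
    action has no interval and is retained (interval NaN). By default the
    interval is measured against the previous *retained* action, so one
    artifactual burst cannot invalidate later normal actions; set
    ``chain_to_retained=False`` to measure against the raw predecessor.
    """
    out = _ensure_validity_columns(events)
    acts = out[out["event_type"] == "action_onset"].sort_values("time_s")
    out["interval_s"] = np.nan
    prev_retained = None
    prev_raw = None
    for i, row in acts.iterrows():
        t = float(row["time_s"])
        ref = prev_retained if chain_to_retained else prev_raw
        if ref is None:
            prev_retained = t
            prev_raw = t
            continue
        iv = t - ref
        out.loc[i, "interval_s"] = iv
        if iv < min_iti:
            out.loc[i, ["valid", "exclusion_reason"]] = [False, "short_interval"]
        elif iv > max_iti:
            out.loc[i, ["valid", "exclusion_reason"]] = [False, "long_interval"]
        else:
            prev_retained = t
        prev_raw = t
    return out


def check_participant_validity(
    valid_counts: Mapping[str, int], min_trials: int = MIN_VALID_TRIALS
) -> bool:
    """Libet participant inclusion: include unless any condition has *fewer
    than* ``min_trials`` valid trials (exactly 20 is included). The elbow
    task applies no such threshold."""
    return all(int(c) >= min_trials for c in valid_counts.values())


def attach_phases(
    events: pd.DataFrame,
    resp: RespPhaseSeries | None,
    cardiac: CardiacCycleTable | None,
    task: str | None = None,
) -> pd.DataFrame:
    """Attach nearest-sample respiratory phase and formula-based cardiac
    phase to each event, with validity inherited from cycle exclusions, plus
    the task's interval covariate (Libet: dot-onset-to-action latency,
    assigned to both events of the trial; elbow: time since previous action).
    """
    out = _ensure_validity_columns(events)
    t = out["time_s"].to_numpy(dtype=float)

    if resp is not None:
        ph, ok = resp.lookup(t)
        out["resp_phase"] = ph
        out["resp_valid"] = ok
    else:
        out["resp_phase"] = np.nan
        out["resp_valid"] = False

    if cardiac is not None:
        cph, cok = extract_cardiac_phase(cardiac, t)
        out["cardiac_phase"] = cph
        out["cardiac_valid"] = cok
    else:
        out["cardiac_phase"] = np.nan
        out["cardiac_valid"] = False

    task = task or (out["task"].iloc[0] if len(out) else "libet")
    out["interval_covariate"] = np.nan
    if task == "libet":
        for trial, grp in out.groupby("trial_index"):
            onsets = grp[grp["event_type"] == "dot_onset"]
            acts = grp[grp["event_type"].isin(["key_press", "key_release"])]
            if len(onsets) == 1 and len(acts) >= 1:
                latency = float(acts["time_s"].max()) - float(onsets["time_s"].iloc[0])
                out.loc[grp.index, "interval_covariate"] = latency
    else:
        acts = out[out["event_type"] == "action_onset"].sort_values("time_s")
        out.loc[acts.index[1:], "interval_covariate"] = np.diff(acts["time_s"].to_numpy())
    return out
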
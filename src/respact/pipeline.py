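"""End-to-end study orchestration and the Monte-Carlo validation studies.

``run_study`` composes the full analysis: simulate (or read) per-participant
recordings, preprocess to respiratory/cardiac phase, apply behavioral
validity rules, run the surrogate-based circular tests, Moore paired
comparisons, state-ratio analyses, peri-event breathing intervals,
trial-by-trial residualized correlations, and individual-difference tables,
writing tidy CSV tables plus a JSON manifest.

``run_calibration_study`` / ``run_moore_calibration`` / ``run_confound_study``
are the simulation studies that validate the inferential machinery: type-I
calibration of the circular-shift surrogate test under the
exhalation-duration bias, power against von Mises coupling, Moore-test
calibration, and interval-confound removal by phase residualization. The
calibration path simulates at the cycle-table level (exact analytic phase,
no signal rendering) because it is the statistic being calibrated, not the
Hilbert pipeline.
"""

from __future__ import annotations

import dataclasses
import json
import time
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .circular import (
    circ_corr,
    circ_mean,
    fdr_adjust,
    fisher_z,
    group_surrogate_test,
    group_t,
    moores_paired_test,
    residualize_phase,
)
from .errors import SchemaError, StageError
from .events import (
    attach_phases,
    check_participant_validity,
    detect_joystick_onsets,
    filter_elbow_trials,
    filter_libet_trials,
)
from .preprocess import (
    CardiacCycleTable,
    SignalTrace,
    align_airflow,
    apply_cycle_exclusions,
    bandpass,
    compute_rmssd,
    detect_r_peaks,
    exclude_cycle_outliers,
    exclude_rr_outliers,
    extract_cardiac_phase,
    extract_resp_phase,
)
from .states import (
    baseline_exhalation_ratio,
    baseline_systole_ratio,
    exhalation_ratio,
    individual_difference_correlations,
    paired_t_vs_baseline,
    peri_event_breathing_intervals,
    phase_lock_indices,
    rm_anova_2way,
    systole_ratio,
)
from .synth import (
    EVENT_COLUMNS,
    GroundTruth,
    SimConfig,
    simulate_cardiac,
    simulate_elbow_session,
    simulate_libet_session,
    simulate_resp_cycles,
    simulate_respiration,
)

LIBET_CONDITIONS = ("key_press", "key_release")
ELBOW_CONDITIONS = ("pull", "push")

# seconds of recording budgeted per trial (generous so self-chosen waiting
# times never outrun the recording)
_LIBET_S_PER_TRIAL = 24.0
_ELBOW_S_PER_TRIAL = 18.0


@dataclass(frozen=True)
class RunConfig:
    """Study-level configuration; the analysis defaults are 1000 surrogates,
    10,000 Moore permutations, alpha 0.05, FDR on."""

    seed: int = 0
    n_participants: int = 28
    tasks: tuple[str, ...] = ("libet", "elbow")
    libet_trials: int = 40
    elbow_trials: int = 40
    sim: SimConfig = field(default_factory=SimConfig)
    respiratory: bool = True
    cardiac: bool = True
    state: bool = True
    trial_by_trial: bool = True
    individual_differences: bool = True
    n_surrogates: int = 1000
    n_permutations: int = 10000
    alpha: float = 0.05
    fdr: bool = True
    outdir: str | None = None


@dataclass
class StudyReport:
    tables: dict[str, pd.DataFrame]
    manifest: dict


def truth_lookup(truth: GroundTruth):
    """Phase lookup on the exact piecewise-linear ground-truth phase."""

    def lookup(times):
        ph = truth.phase_at(times)
        return ph, np.isfinite(ph)

    return lookup


def simulate_truth_only(config: SimConfig) -> GroundTruth:
    """Cycle-table-only simulation (analytic phase, no rendered signals)."""
    return GroundTruth(cycle_table=simulate_resp_cycles(config), fs=config.fs)


# ---------------------------------------------------------------------------
# Participant-level simulation + preprocessing
# ---------------------------------------------------------------------------

def _child_seeds(master_seed: int, tag: int, shape) -> np.ndarray:
    rng = np.random.default_rng([int(master_seed), int(tag)])
    return rng.integers(0, 2 ** 31 - 1, size=shape)


def preprocess_recording(belt: SignalTrace, airflow: SignalTrace,
                         ecg: SignalTrace | None):
    """Standard preprocessing chain: band-pass, airflow alignment, Hilbert
    respiratory phase with IQR cycle fencing, R-peak detection with RR
    fencing. Returns (resp_series, cycle_table, cardiac_table, alignment)."""
    belt_f = bandpass(belt, 0.1, 3.0)
    air_f = bandpass(airflow, 0.1, 3.0)
    aligned, alignment = align_airflow(air_f, belt_f)
    series, cycles = extract_resp_phase(aligned)
    cycles = exclude_cycle_outliers(cycles)
    series = apply_cycle_exclusions(series, cycles)
    cardiac = None
    if ecg is not None:
        ecg_f = bandpass(ecg, 0.5, 40.0)
        cardiac = exclude_rr_outliers(detect_r_peaks(ecg_f))
    return series, cycles, cardiac, alignment


def _simulate_condition(base: SimConfig, seed: int, task: str, condition: str,
                        n_trials: int, with_cardiac: bool):
    per_trial = _LIBET_S_PER_TRIAL if task == "libet" else _ELBOW_S_PER_TRIAL
    cfg = replace(base, seed=int(seed), duration=n_trials * per_trial + 60.0)
    belt, airflow, truth = simulate_respiration(cfg)
    ecg = None
    if with_cardiac:
        ecg, rpeaks = simulate_cardiac(cfg)
        truth.rpeak_times = rpeaks
    if task == "libet":
        events = simulate_libet_session(cfg, truth, condition, n_trials)
        joystick = None
    else:
        events, joystick = simulate_elbow_session(cfg, truth, condition, n_trials)
    return cfg, belt, airflow, ecg, joystick, events, truth


def _analyze_condition(task, condition, events_sim, belt, airflow, ecg, joystick):
    """Preprocess one simulated recording and return attached-phase events
    plus the physiological tables."""
    series, cycles, cardiac, alignment = preprocess_recording(belt, airflow, ecg)
    if task == "elbow":
        detected = detect_joystick_onsets(joystick, condition)
        filtered = filter_elbow_trials(detected)
    else:
        filtered = filter_libet_trials(events_sim, condition)
    attached = attach_phases(filtered, series, cardiac, task=task)
    return {
        "events": attached,
        "series": series,
        "cycles": cycles,
        "cardiac": cardiac,
        "alignment": alignment,
    }


def _timings(task: str) -> list[tuple[str, list[str]]]:
    if task == "libet":
        return [("dot_onset", ["dot_onset"]), ("action", ["key_press", "key_release"])]
    return [("action", ["action_onset"])]


def _event_times_for_timing(ev: pd.DataFrame, task: str, condition: str,
                            timing_types: list[str]) -> np.ndarray:
    sel = ev[ev["valid"] & ev["event_type"].isin(timing_types)]
    if task == "libet" and timing_types == ["key_press", "key_release"]:
        wanted = "key_press" if condition == "key_press" else "key_release"
        sel = sel[sel["event_type"] == wanted]
    return sel["time_s"].to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# run_study
# ---------------------------------------------------------------------------

def run_study(config: RunConfig) -> StudyReport:
    """Execute the full pipeline for a simulated multi-participant study.

    Any stage failure raises :class:`StageError` carrying the stage name;
    tables completed before the failure are preserved in the output
    directory when one is configured.
    """
    t_start = time.time()
    tables: dict[str, pd.DataFrame] = {}
    log: list[str] = []
    manifest = {
        "config": _config_dict(config),
        "seed": config.seed,
        "version": __version__,
        "started": t_start,
        "log": log,
    }

    def _finish_stage(name):
        log.append(name)
        if config.outdir:
            write_report(StudyReport(tables, manifest), config.outdir)

    part_seeds = _child_seeds(config.seed, 11, (config.n_participants, 4))
    surro_seeds = _child_seeds(config.seed, 12, 64)
    perm_seeds = _child_seeds(config.seed, 13, 64)
    study_rng = np.random.default_rng([config.seed, 14])

    # ---- simulate + preprocess ------------------------------------------
    data: dict = {}
    exclusions = []
    try:
        for task in config.tasks:
            conds = LIBET_CONDITIONS if task == "libet" else ELBOW_CONDITIONS
            n_trials = config.libet_trials if task == "libet" else config.elbow_trials
            data[task] = {}
            for ci, cond in enumerate(conds):
                per_part = []
                for p in range(config.n_participants):
                    cfg, belt, airflow, ecg, joy, ev, truth = _simulate_condition(
                        config.sim, part_seeds[p, 2 * (task == "elbow") + ci],
                        task, cond, n_trials, config.cardiac,
                    )
                    res = _analyze_condition(task, cond, ev, belt, airflow, ecg, joy)
                    res["participant"] = p
                    res["truth"] = truth
                    per_part.append(res)
                    bad = res["events"][~res["events"]["valid"]]
                    for _, row in bad.iterrows():
                        exclusions.append(
                            {"participant": p, "task": task, "condition": cond,
                             "trial_index": row["trial_index"],
                             "reason": row["exclusion_reason"]}
                        )
                data[task][cond] = per_part
    except Exception as exc:  # noqa: BLE001 - rewrap with stage name
        raise StageError("simulate_preprocess", str(exc)) from exc
    tables["exclusions"] = pd.DataFrame(
        exclusions, columns=["participant", "task", "condition", "trial_index", "reason"]
    )
    _finish_stage("simulate_preprocess")

    # ---- participant inclusion (Libet only) -----------------------------
    included: dict[str, list[int]] = {}
    for task in config.tasks:
        if task == "libet":
            keep = []
            for p in range(config.n_participants):
                counts = {}
                for cond in LIBET_CONDITIONS:
                    ev = data[task][cond][p]["events"]
                    action = "key_press" if cond == "key_press" else "key_release"
                    counts[cond] = int(
                        (ev["valid"] & (ev["event_type"] == action)).sum()
                    )
                if check_participant_validity(counts):
                    keep.append(p)
            included[task] = keep
        else:
            included[task] = list(range(config.n_participants))
    manifest["included_participants"] = included
    _finish_stage("participant_inclusion")

    # ---- circular tests --------------------------------------------------
    try:
        rows = []
        signals = [("resp", True)] + ([("cardiac", True)] if config.cardiac else [])
        si = 0
        for task in config.tasks:
            conds = LIBET_CONDITIONS if task == "libet" else ELBOW_CONDITIONS
            for signal, _ in signals:
                if signal == "resp" and not config.respiratory:
                    continue
                for cond in conds:
                    for timing, types in _timings(task):
                        participants = []
                        for p in included[task]:
                            res = data[task][cond][p]
                            times = _event_times_for_timing(res["events"], task, cond, types)
                            if signal == "resp":
                                lookup = res["series"].lookup
                                span = res["series"].span
                            else:
                                cc = res["cardiac"]
                                lookup = lambda t, cc=cc: extract_cardiac_phase(cc, t)
                                span = (cc.rpeak_times[0], cc.rpeak_times[-1])
                            participants.append((times, lookup, span))
                        result = group_surrogate_test(
                            participants, n_surrogates=config.n_surrogates,
                            seed=int(surro_seeds[si % 64]),
                        )
                        si += 1
                        rows.append(
                            {"task": task, "signal": signal, "condition": cond,
                             "timing": timing, "observed_m": result.observed_m,
                             "surrogate_mean": float(result.surrogate_ms.mean()),
                             "p": result.p_two_tailed,
                             "n_participants": len(participants)}
                        )
        circ = pd.DataFrame(rows)
        if config.fdr and len(circ):
            circ["p_fdr"] = np.nan
            for (task, signal), grp in circ.groupby(["task", "signal"]):
                circ.loc[grp.index, "p_fdr"] = fdr_adjust(grp["p"].to_numpy())
        tables["circular_tests"] = circ
    except Exception as exc:  # noqa: BLE001
        raise StageError("circular_tests", str(exc)) from exc
    _finish_stage("circular_tests")

    # ---- Moore paired comparisons ---------------------------------------
    try:
        rows = []
        mi = 0
        for task in config.tasks:
            conds = LIBET_CONDITIONS if task == "libet" else ELBOW_CONDITIONS
            pairs_a, pairs_b = [], []
            for p in included[task]:
                means = []
                for cond in conds:
                    ev = data[task][cond][p]["events"]
                    _, types = _timings(task)[-1]
                    times_sel = ev[ev["valid"] & ev["event_type"].isin(types)
                                   & ev["resp_valid"]]
                    summ = circ_mean(times_sel["resp_phase"].to_numpy())
                    means.append(summ.mean_angle if summ.defined else np.nan)
                if np.all(np.isfinite(means)):
                    pairs_a.append(means[0])
                    pairs_b.append(means[1])
            if len(pairs_a) >= 5:
                res = moores_paired_test(
                    np.asarray(pairs_a), np.asarray(pairs_b),
                    n_permutations=config.n_permutations,
                    seed=int(perm_seeds[mi % 64]),
                )
                mi += 1
                rows.append({"task": task, "comparison": f"{conds[0]}_vs_{conds[1]}",
                             "timing": "action", "r_stat": res.r_stat, "p": res.p,
                             "n_pairs": res.n_pairs})
        moore = pd.DataFrame(rows)
        if config.fdr and len(moore):
            moore["p_fdr"] = fdr_adjust(moore["p"].to_numpy())
        tables["moore_tests"] = moore
    except Exception as exc:  # noqa: BLE001
        raise StageError("moore_tests", str(exc)) from exc
    _finish_stage("moore_tests")

    # ---- state ratios, t-tests, ANOVA, peri-event intervals -------------
    if config.state:
        try:
            ratio_rows, peri_rows = [], []
            for task in config.tasks:
                conds = LIBET_CONDITIONS if task == "libet" else ELBOW_CONDITIONS
                for cond in conds:
                    for p in included[task]:
                        res = data[task][cond][p]
                        ev = res["events"]
                        for timing, types in _timings(task):
                            if task == "libet" and timing == "action":
                                wanted = ["key_press" if cond == "key_press" else "key_release"]
                            else:
                                wanted = types
                            sel = ev[ev["valid"] & ev["event_type"].isin(wanted)]
                            phases = sel.loc[sel["resp_valid"], "resp_phase"].to_numpy()
                            times = sel["time_s"].to_numpy(dtype=float)
                            row = {
                                "task": task, "condition": cond, "timing": timing,
                                "participant": p, "n_events": len(sel),
                                "exhalation_ratio": exhalation_ratio(phases),
                                "baseline_exhalation_ratio":
                                    baseline_exhalation_ratio(res["cycles"]),
                            }
                            if config.cardiac and res["cardiac"] is not None:
                                row["systole_ratio"] = systole_ratio(times, res["cardiac"])
                                row["baseline_systole_ratio"] = baseline_systole_ratio(
                                    res["cardiac"]
                                )
                            ratio_rows.append(row)
                            peri = peri_event_breathing_intervals(times, res["cycles"])
                            okp = peri["valid"]
                            if okp.any():
                                peri_rows.append(
                                    {"task": task, "condition": cond, "timing": timing,
                                     "participant": p,
                                     "before1": peri.loc[okp, "before1"].mean(),
                                     "during": peri.loc[okp, "during"].mean(),
                                     "after1": peri.loc[okp, "after1"].mean()}
                                )
            ratios = pd.DataFrame(ratio_rows)
            tables["state_ratios"] = ratios

            test_rows, anova_frames = [], []
            for task in config.tasks:
                sub = ratios[ratios["task"] == task]
                measures = [("exhalation_ratio", "baseline_exhalation_ratio")]
                if config.cardiac and "systole_ratio" in ratios:
                    measures.append(("systole_ratio", "baseline_systole_ratio"))
                for value_col, base_col in measures:
                    for (cond, timing), grp in sub.groupby(["condition", "timing"]):
                        res = paired_t_vs_baseline(
                            grp[value_col].to_numpy(), grp[base_col].to_numpy()
                        )
                        test_rows.append(
                            {"task": task, "measure": value_col, "condition": cond,
                             "timing": timing, "t": res.t, "p": res.p,
                             "cohen_d": res.cohen_d, "n": res.n}
                        )
                    if sub["timing"].nunique() > 1 and sub["condition"].nunique() > 1:
                        an = rm_anova_2way(
                            sub.rename(columns={value_col: "value"}),
                            dv="value", subject="participant",
                        )
                        an.insert(0, "measure", value_col)
                        an.insert(0, "task", task)
                        anova_frames.append(an)
            tests = pd.DataFrame(test_rows)
            if config.fdr and len(tests):
                tests["p_fdr"] = np.nan
                for (task, meas), grp in tests.groupby(["task", "measure"]):
                    ok = grp["p"].notna()
                    if ok.any():
                        tests.loc[grp.index[ok], "p_fdr"] = fdr_adjust(
                            grp.loc[ok, "p"].to_numpy()
                        )
            tables["state_tests"] = tests
            if anova_frames:
                tables["state_anova"] = pd.concat(anova_frames, ignore_index=True)

            peri = pd.DataFrame(peri_rows)
            tables["peri_event_intervals"] = peri
            anovas = []
            for task in config.tasks:
                subp = peri[(peri["task"] == task) & (peri["timing"] == "action")]
                if len(subp) and subp["condition"].nunique() > 1:
                    long = subp.melt(
                        id_vars=["participant", "condition"],
                        value_vars=["before1", "during", "after1"],
                        var_name="interval_position", value_name="value",
                    )
                    an = rm_anova_2way(long, dv="value", subject="participant",
                                       factor_a="condition", factor_b="interval_position")
                    an.insert(0, "task", task)
                    anovas.append(an)
            if anovas:
                tables["peri_event_anova"] = pd.concat(anovas, ignore_index=True)
        except Exception as exc:  # noqa: BLE001
            raise StageError("state_analysis", str(exc)) from exc
        _finish_stage("state_analysis")

    # ---- trial-by-trial residualized circular correlations (Libet) ------
    if config.trial_by_trial and "libet" in config.tasks:
        try:
            rows = []
            for p in included["libet"]:
                for cond in LIBET_CONDITIONS:
                    ev = data["libet"][cond][p]["events"]
                    action = "key_press" if cond == "key_press" else "key_release"
                    for pairing in ("stim_action", "action_next_stim"):
                        ph_s, ph_a, cov = _phase_pairs(ev, action, pairing)
                        if ph_s.size < 5:
                            continue
                        try:
                            z_raw = fisher_z(circ_corr(ph_s, ph_a))
                            z_res = fisher_z(
                                circ_corr(residualize_phase(ph_s, cov),
                                          residualize_phase(ph_a, cov))
                            )
                        except Exception:  # undefined means at tiny n
                            continue
                        rows.append({"participant": p, "condition": cond,
                                     "pairing": pairing, "n_pairs": ph_s.size,
                                     "z_raw": z_raw, "z_residualized": z_res})
            tbt = pd.DataFrame(rows)
            tables["trial_by_trial"] = tbt
            trows = []
            for pairing, grp in tbt.groupby("pairing"):
                # average z across conditions within participant, then group t
                per = grp.groupby("participant")["z_residualized"].mean()
                if len(per) >= 2:
                    res = group_t(per.to_numpy())
                    trows.append({"pairing": pairing, "mean_z": float(per.mean()),
                                  "t": res.t, "p": res.p, "cohen_d": res.cohen_d,
                                  "n": res.n})
            tables["trial_by_trial_tests"] = pd.DataFrame(trows)
        except Exception as exc:  # noqa: BLE001
            raise StageError("trial_by_trial", str(exc)) from exc
        _finish_stage("trial_by_trial")

    # ---- individual differences -----------------------------------------
    if config.individual_differences:
        try:
            rows = []
            task0 = config.tasks[0]
            conds = LIBET_CONDITIONS if task0 == "libet" else ELBOW_CONDITIONS
            ages = study_rng.uniform(20, 45, config.n_participants)
            for p in included[task0]:
                locks, diffs = [], []
                breaths, rr_means, rr_rmssd = [], [], []
                for cond in conds:
                    res = data[task0][cond][p]
                    ev = res["events"]
                    _, types = _timings(task0)[-1]
                    sel = ev[ev["valid"] & ev["event_type"].isin(types) & ev["resp_valid"]]
                    baseline = res["series"].phase[res["series"].valid]
                    idx = phase_lock_indices(sel["resp_phase"].to_numpy(), baseline)
                    locks.append(idx.locking_strength)
                    diffs.append(idx.phase_difference)
                    okc = ~res["cycles"]["excluded"]
                    breaths.append(res["cycles"].loc[okc, "t_total"].to_numpy())
                    if res["cardiac"] is not None:
                        rr = res["cardiac"].rr[~res["cardiac"].excluded]
                        rr_means.append(rr.mean())
                        rr_rmssd.append(compute_rmssd(rr))
                breath_all = np.concatenate(breaths)
                row = {
                    "participant": p, "age": ages[p],
                    "locking_strength": float(np.nanmean(locks)),
                    "phase_difference": float(np.nanmean(diffs)),
                    "mean_breath_interval": float(breath_all.mean()),
                    "breathing_rmssd": compute_rmssd(breath_all),
                }
                if rr_means:
                    row["mean_rr"] = float(np.mean(rr_means))
                    row["hrv_rmssd"] = float(np.mean(rr_rmssd))
                rows.append(row)
            idx_table = pd.DataFrame(rows)
            tables["individual_indices"] = idx_table
            preds = ["age", "mean_breath_interval", "breathing_rmssd"]
            if "mean_rr" in idx_table:
                preds += ["mean_rr", "hrv_rmssd"]
            if len(idx_table) >= 10:
                tables["individual_correlations"] = individual_difference_correlations(
                    idx_table, ["locking_strength"], preds, fdr=config.fdr
                )
        except Exception as exc:  # noqa: BLE001
            raise StageError("individual_differences", str(exc)) from exc
        _finish_stage("individual_differences")

    manifest["elapsed_s"] = time.time() - t_start
    report = StudyReport(tables, manifest)
    if config.outdir:
        write_report(report, config.outdir)
    return report


def _phase_pairs(ev: pd.DataFrame, action_type: str, pairing: str):
    """Paired (stimulus phase, action phase, interval covariate) arrays.

    ``stim_action``: dot onset and action within the same trial, covariate =
    onset-to-action latency. ``action_next_stim``: action phase in trial k
    and dot-onset phase in trial k+1, covariate = action-to-next-onset time.
    """
    ok = ev[ev["valid"] & ev["resp_valid"]]
    onsets = ok[ok["event_type"] == "dot_onset"].set_index("trial_index")
    acts = ok[ok["event_type"] == action_type].set_index("trial_index")
    if pairing == "stim_action":
        common = onsets.index.intersection(acts.index)
        ph_s = onsets.loc[common, "resp_phase"].to_numpy()
        ph_a = acts.loc[common, "resp_phase"].to_numpy()
        cov = (acts.loc[common, "time_s"] - onsets.loc[common, "time_s"]).to_numpy()
        return ph_s, ph_a, cov
    nxt = onsets.index.intersection(acts.index + 1)
    prev = nxt - 1
    ph_a = acts.loc[prev, "resp_phase"].to_numpy()
    ph_s = onsets.loc[nxt, "resp_phase"].to_numpy()
    cov = (onsets.loc[nxt, "time_s"].to_numpy() - acts.loc[prev, "time_s"].to_numpy())
    return ph_a, ph_s, cov


def _config_dict(config: RunConfig) -> dict:
    d = dataclasses.asdict(config)
    d["sim"] = dataclasses.asdict(config.sim)
    return d


# ---------------------------------------------------------------------------
# Monte-Carlo validation studies
# ---------------------------------------------------------------------------

def run_calibration_study(
    kappa_values=(None, 0.5, 1.0, 2.0),
    mu: float = 7 * np.pi / 4,
    n_replicates: int = 100,
    n_participants: int = 28,
    n_events: int = 40,
    n_surrogates: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    sim: SimConfig | None = None,
) -> pd.DataFrame:
    """Type-I error / power of the group surrogate test by coupling strength.

    ``kappa = None`` or ``kappa = 0`` rows use uniform-in-time event
    placement -- the no-coupling null in which the exhalation-duration bias
    is fully present; positive kappa rows use von Mises phase coupling at
    ``mu``. Events and phases come from the analytic cycle-table simulation;
    each replicate is an independent simulated study. Returns one row per
    kappa with the rejection rate at ``alpha`` and its binomial Monte-Carlo
    standard error.
    """
    base = sim if sim is not None else SimConfig()
    rows = []
    for ki, kappa in enumerate(kappa_values):
        part_seeds = _child_seeds(seed, 100 + ki, (n_replicates, n_participants))
        surro_seeds = _child_seeds(seed, 200 + ki, n_replicates)
        if kappa is None or kappa == 0:
            cfg0 = replace(base, coupling_mode="uniform_time", kappa=0.0)
        else:
            cfg0 = replace(base, coupling_mode="von_mises", kappa=float(kappa),
                           mu=float(np.mod(mu, 2 * np.pi)))
        duration = n_events * _LIBET_S_PER_TRIAL + 60.0
        reject = 0
        for rep in range(n_replicates):
            participants = []
            for p in range(n_participants):
                cfg = replace(cfg0, seed=int(part_seeds[rep, p]), duration=duration)
                truth = simulate_truth_only(cfg)
                events = simulate_libet_session(cfg, truth, "key_press", n_events)
                times = events.loc[events["event_type"] == "key_press", "time_s"].to_numpy()
                participants.append((times, truth_lookup(truth), truth.span))
            res = group_surrogate_test(
                participants, n_surrogates=n_surrogates, seed=int(surro_seeds[rep])
            )
            reject += res.p_two_tailed <= alpha
        rate = reject / n_replicates
        rows.append(
            {"kappa": np.nan if kappa is None else float(kappa),
             "mode": "uniform_time" if kappa is None else "von_mises",
             "rejection_rate": rate,
             "mc_se": float(np.sqrt(max(rate * (1 - rate), 1e-12) / n_replicates)),
             "n_replicates": n_replicates, "n_participants": n_participants,
             "n_events": n_events, "n_surrogates": n_surrogates, "alpha": alpha}
        )
    return pd.DataFrame(rows)


def run_moore_calibration(
    n_replicates: int = 500,
    n_pairs: int = 20,
    n_permutations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Type-I error of the randomized Moore test under independent uniform
    paired angles."""
    rng = np.random.default_rng([seed, 300])
    perm_seeds = _child_seeds(seed, 301, n_replicates)
    reject = 0
    for rep in range(n_replicates):
        a = rng.uniform(0, 2 * np.pi, n_pairs)
        b = rng.uniform(0, 2 * np.pi, n_pairs)
        res = moores_paired_test(a, b, n_permutations=n_permutations,
                                 seed=int(perm_seeds[rep]))
        reject += res.p <= alpha
    return reject / n_replicates


def run_confound_study(
    n_participants: int = 20,
    n_events: int = 200,
    seed: int = 0,
    slope: float = 0.5,
    noise_kappa: float = 4.0,
) -> dict:
    """Interval-confound removal by phase residualization.

    Confounded arm: stimulus and action mean phases are both linear in the
    inter-event interval (slope rad/s) plus independent von Mises noise, with
    no genuine phase-phase coupling -- any raw circular correlation is
    interval-driven. Coupled arm: both phases share a uniform per-event phase
    (genuine coupling) while the interval is independent. Reports group mean
    |Fisher z| after residualization in the confounded arm, and the fraction
    of the raw mean z retained after residualization in the coupled arm.
    """
    rng = np.random.default_rng([seed, 400])
    z_conf_raw, z_conf_res, z_coup_raw, z_coup_res = [], [], [], []
    for p in range(n_participants):
        c = np.clip(rng.normal(5.0, 0.8, n_events), 2.56, None)
        off = rng.uniform(0, 2 * np.pi)
        e1 = rng.vonmises(0.0, noise_kappa, n_events)
        e2 = rng.vonmises(0.0, noise_kappa, n_events)
        ph_s = np.mod(slope * c + off + e1, 2 * np.pi)
        ph_a = np.mod(slope * c + off + 1.0 + e2, 2 * np.pi)
        z_conf_raw.append(fisher_z(circ_corr(ph_s, ph_a)))
        z_conf_res.append(
            fisher_z(circ_corr(residualize_phase(ph_s, c), residualize_phase(ph_a, c)))
        )

        eta = rng.uniform(0, 2 * np.pi, n_events)
        c2 = np.clip(rng.normal(5.0, 0.8, n_events), 2.56, None)
        f1 = rng.vonmises(0.0, noise_kappa, n_events)
        f2 = rng.vonmises(0.0, noise_kappa, n_events)
        qs = np.mod(eta + f1, 2 * np.pi)
        qa = np.mod(eta + 1.0 + f2, 2 * np.pi)
        z_coup_raw.append(fisher_z(circ_corr(qs, qa)))
        z_coup_res.append(
            fisher_z(circ_corr(residualize_phase(qs, c2), residualize_phase(qa, c2)))
        )
    return {
        "confound_mean_abs_z_residualized": float(np.mean(np.abs(z_conf_res))),
        "confound_mean_z_raw": float(np.mean(z_conf_raw)),
        "coupled_mean_z_raw": float(np.mean(z_coup_raw)),
        "coupled_mean_z_residualized": float(np.mean(z_coup_res)),
        "coupled_retained_fraction": float(np.mean(z_coup_res) / np.mean(z_coup_raw)),
        "n_participants": n_participants,
        "n_events": n_events,
    }


# ---------------------------------------------------------------------------
# Session I/O
# ---------------------------------------------------------------------------

def read_session(path: str | Path):
    """Read a session directory written by :func:`respact.synth.write_session`.

    Returns (traces, events, sidecar). Schema violations raise
    :class:`SchemaError` naming the offending file/field; unknown extra
    columns are accepted with a warning.
    """
    path = Path(path)
    sidecar_path = path / "session.json"
    if not sidecar_path.exists():
        raise SchemaError(f"{sidecar_path}: missing session sidecar")
    sidecar = json.loads(sidecar_path.read_text())
    for fld in ("fs", "seed"):
        if fld not in sidecar:
            raise SchemaError(f"{sidecar_path}: missing required field '{fld}'")
    fs = float(sidecar["fs"])

    traces = {}
    for name in sidecar.get("channels", []):
        f = path / f"{name}.csv"
        if not f.exists():
            raise SchemaError(f"{f}: channel listed in sidecar but file missing")
        df = pd.read_csv(f)
        for col in ("time_s", "value"):
            if col not in df.columns:
                raise SchemaError(f"{f}: missing required column '{col}'")
        extra = set(df.columns) - {"time_s", "value"}
        if extra:
            warnings.warn(f"{f}: ignoring extra columns {sorted(extra)}", stacklevel=2)
        t0 = float(df["time_s"].iloc[0]) if len(df) else 0.0
        traces[name] = SignalTrace(df["value"].to_numpy(), fs, label=name, t0=t0)

    events_path = path / "events.csv"
    if not events_path.exists():
        raise SchemaError(f"{events_path}: missing events file")
    events = pd.read_csv(events_path)
    for col in EVENT_COLUMNS:
        if col not in events.columns:
            raise SchemaError(f"{events_path}: missing required column '{col}'")
    extra = set(events.columns) - set(EVENT_COLUMNS) - {
        "true_phase", "cross_sample", "valid", "exclusion_reason"}
    if extra:
        warnings.warn(f"{events_path}: ignoring extra columns {sorted(extra)}",
                      stacklevel=2)
    return traces, events, sidecar


def write_report(report: StudyReport, outdir: str | Path) -> Path:
    """Write every result table as CSV plus the JSON run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in report.tables.items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    (outdir / "manifest.json").write_text(
        json.dumps(report.manifest, indent=2, default=str)
    )
    return outdir
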
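"""State-based analyses: exhalation and systole event ratios against
temporal baselines, peri-event breathing intervals, paired t-tests and
two-way repeated-measures ANOVA with generalized eta squared, phase-locking
indices, and individual-difference correlations.

The baseline logic: if events were unrelated to physiology, the fraction of
events falling in a state (exhalation; the 200-400 ms post-R systolic
window) would match the fraction of *time* the participant spends in that
state. Event ratios are therefore compared to these temporal baselines, not
to 0.5.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sstats

from .circular import circ_mean, fdr_adjust, wrap_pm_pi
from .errors import InsufficientDataError
from .preprocess import CardiacCycleTable

SYSTOLE_WINDOW = (0.200, 0.400)  # s after the R-peak


# ---------------------------------------------------------------------------
# Exhalation / systole ratios and their temporal baselines
# ---------------------------------------------------------------------------

def exhalation_ratio(event_phases: np.ndarray) -> float:
    """Fraction of events with respiratory phase in [pi, 2*pi) (exhalation).
    The inhalation ratio is its complement and is not reported separately."""
    ph = np.asarray(event_phases, dtype=float)
    ph = ph[np.isfinite(ph)]
    if ph.size == 0:
        warnings.warn("exhalation_ratio undefined: no valid events", stacklevel=2)
        return float("nan")
    ph = np.mod(ph, 2 * np.pi)
    return float(np.mean((ph >= np.pi) & (ph < 2 * np.pi)))


def baseline_exhalation_ratio(cycles: pd.DataFrame) -> float:
    """Temporal exhalation proportion Sum(t_ex)/Sum(t_total) over valid cycles."""
    ok = ~cycles["excluded"].to_numpy(dtype=bool)
    if not ok.any():
        warnings.warn("baseline exhalation ratio undefined: no valid cycles", stacklevel=2)
        return float("nan")
    return float(cycles.loc[ok, "t_ex"].sum() / cycles.loc[ok, "t_total"].sum())


def systole_ratio(
    event_times: np.ndarray,
    cardiac: CardiacCycleTable,
    window: tuple[float, float] = SYSTOLE_WINDOW,
) -> float:
    """Fraction of events falling 200-400 ms after the preceding R-peak.
    Events outside the peak span or inside excluded RR intervals are dropped."""
    t = np.asarray(event_times, dtype=float)
    peaks = cardiac.rpeak_times
    idx = np.searchsorted(peaks, t, side="right") - 1
    inside = (idx >= 0) & (idx < cardiac.rr.size)
    i = np.clip(idx, 0, cardiac.rr.size - 1)
    keep = inside & ~cardiac.excluded[i]
    if not keep.any():
        warnings.warn("systole_ratio undefined: no valid events", stacklevel=2)
        return float("nan")
    offset = t[keep] - peaks[i[keep]]
    return float(np.mean((offset >= window[0]) & (offset <= window[1])))


def baseline_systole_ratio(
    cardiac: CardiacCycleTable, window: tuple[float, float] = SYSTOLE_WINDOW
) -> float:
    """Temporal proportion of the systolic window, time-weighted across valid
    RR intervals: each interval contributes min(w1, RR) - w0 (clipped at 0)
    seconds of systole out of its RR seconds, so an interval shorter than the
    window contributes only its truncated overlap."""
    ok = ~cardiac.excluded
    if not ok.any():
        warnings.warn("baseline systole ratio undefined: no valid intervals", stacklevel=2)
        return float("nan")
    rr = cardiac.rr[ok]
    w0, w1 = window
    contrib = np.clip(np.minimum(rr, w1) - w0, 0.0, w1 - w0)
    return float(contrib.sum() / rr.sum())


def baseline_systole_ratio_per_interval(
    cardiac: CardiacCycleTable, window: tuple[float, float] = SYSTOLE_WINDOW
) -> float:
    """Secondary variant: unweighted mean of per-interval window proportions."""
    ok = ~cardiac.excluded
    rr = cardiac.rr[ok]
    w0, w1 = window
    contrib = np.clip(np.minimum(rr, w1) - w0, 0.0, w1 - w0)
    return float(np.mean(contrib / rr))


# ---------------------------------------------------------------------------
# Peri-event breathing intervals
# ---------------------------------------------------------------------------

def peri_event_breathing_intervals(
    event_times: np.ndarray, cycles: pd.DataFrame
) -> pd.DataFrame:
    """Durations of the breath cycle before, containing, and after each event.

    Edge events (first/last cycle) and events whose host cycle or neighbors
    are excluded get ``valid = False`` and are left out of the triplet
    analysis rather than silently dropped.
    """
    t = np.asarray(event_times, dtype=float)
    troughs = cycles["trough_time"].to_numpy()
    nexts = cycles["next_trough_time"].to_numpy()
    durs = cycles["t_total"].to_numpy()
    excl = cycles["excluded"].to_numpy(dtype=bool)
    idx = np.searchsorted(troughs, t, side="right") - 1
    in_span = (idx >= 0) & (idx < len(cycles)) & (t < nexts[np.clip(idx, 0, len(cycles) - 1)])
    i = np.clip(idx, 0, len(cycles) - 1)
    has_neighbors = (i >= 1) & (i <= len(cycles) - 2)
    ok = in_span & has_neighbors
    im, ip = np.clip(i - 1, 0, len(cycles) - 1), np.clip(i + 1, 0, len(cycles) - 1)
    ok &= ~(excl[i] | excl[im] | excl[ip])
    out = pd.DataFrame(
        {
            "time_s": t,
            "before1": np.where(ok, durs[im], np.nan),
            "during": np.where(ok, durs[i], np.nan),
            "after1": np.where(ok, durs[ip], np.nan),
            "valid": ok,
        }
    )
    return out


# ---------------------------------------------------------------------------
# Group tests
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairedTResult:
    t: float
    p: float
    cohen_d: float
    n: int
    defined: bool = True


def paired_t_vs_baseline(values: np.ndarray, baselines: np.ndarray) -> PairedTResult:
    """Paired t-test of per-participant values against their own baselines,
    with Cohen's d = mean difference / SD of differences."""
    v = np.asarray(values, dtype=float)
    b = np.asarray(baselines, dtype=float)
    if v.size != b.size or v.size < 2:
        raise InsufficientDataError("paired_t_vs_baseline needs >= 2 matched pairs")
    d = v - b
    sd = float(np.std(d, ddof=1))
    if sd == 0:
        t = 0.0 if np.allclose(d, 0) else float("inf") * np.sign(d.mean())
        return PairedTResult(t, float("nan") if t else 1.0, float("nan"), v.size, False)
    t, p = sstats.ttest_rel(v, b)
    return PairedTResult(float(t), float(p), float(d.mean() / sd), v.size)


def rm_anova_2way(
    data: pd.DataFrame,
    dv: str = "value",
    subject: str = "participant",
    factor_a: str = "condition",
    factor_b: str = "timing",
) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA on one observation per cell.

    Standard balanced sum-of-squares decomposition: each effect is tested
    against its own subject-by-effect interaction. Generalized eta squared
    uses SS_effect / (SS_effect + SS_subjects + all error SS terms).
    """
    d = data[[subject, factor_a, factor_b, dv]].copy()
    piv = d.pivot_table(index=subject, columns=[factor_a, factor_b], values=dv)
    if piv.isna().any().any():
        raise InsufficientDataError("rm_anova_2way requires complete cells")
    ns = piv.shape[0]
    if ns < 2:
        raise InsufficientDataError("rm_anova_2way needs >= 2 participants")
    y = piv.to_numpy()
    a_levels = piv.columns.get_level_values(0).unique()
    b_levels = piv.columns.get_level_values(1).unique()
    na, nb = len(a_levels), len(b_levels)
    cube = y.reshape(ns, na, nb)

    g = cube.mean()
    m_s = cube.mean(axis=(1, 2))
    m_a = cube.mean(axis=(0, 2))
    m_b = cube.mean(axis=(0, 1))
    m_sa = cube.mean(axis=2)
    m_sb = cube.mean(axis=1)
    m_ab = cube.mean(axis=0)

    ss_s = na * nb * np.sum((m_s - g) ** 2)
    ss_a = ns * nb * np.sum((m_a - g) ** 2)
    ss_b = ns * na * np.sum((m_b - g) ** 2)
    ss_ab = ns * np.sum((m_ab - m_a[:, None] - m_b[None, :] + g) ** 2)
    ss_sa = nb * np.sum((m_sa - m_s[:, None] - m_a[None, :] + g) ** 2)
    ss_sb = na * np.sum((m_sb - m_s[:, None] - m_b[None, :] + g) ** 2)
    ss_tot = np.sum((cube - g) ** 2)
    ss_sab = ss_tot - (ss_s + ss_a + ss_b + ss_ab + ss_sa + ss_sb)

    err_ss = ss_sa + ss_sb + ss_sab
    rows = []
    for name, ss_eff, df_eff, ss_err, df_err in (
        (factor_a, ss_a, na - 1, ss_sa, (na - 1) * (ns - 1)),
        (factor_b, ss_b, nb - 1, ss_sb, (nb - 1) * (ns - 1)),
        (f"{factor_a}:{factor_b}", ss_ab, (na - 1) * (nb - 1), ss_sab,
         (na - 1) * (nb - 1) * (ns - 1)),
    ):
        ms_eff = ss_eff / df_eff
        ms_err = ss_err / df_err if df_err else np.nan
        f = ms_eff / ms_err if ms_err else np.nan
        p = float(sstats.f.sf(f, df_eff, df_err)) if np.isfinite(f) else float("nan")
        ges = ss_eff / (ss_eff + ss_s + err_ss)
        rows.append(
            {"effect": name, "ss": ss_eff, "df1": df_eff, "df2": df_err,
             "F": float(f), "p": p, "ges": float(ges)}
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Individual-difference indices
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhaseLockIndices:
    """Per participant x condition coupling indices.

    ``phase_difference`` is the circular difference event-mean minus
    baseline-mean, wrapped to (-pi, pi]; ``locking_strength`` is baseline
    circular variance minus event circular variance, so positive values mean
    the events are more phase-concentrated than the recording as a whole.
    """

    phase_difference: float
    locking_strength: float
    defined: bool = True


def phase_lock_indices(
    event_phases: np.ndarray, baseline_phases: np.ndarray
) -> PhaseLockIndices:
    ev = circ_mean(event_phases)
    ba = circ_mean(baseline_phases)
    strength = ba.circ_variance - ev.circ_variance
    if not (ev.defined and ba.defined):
        return PhaseLockIndices(float("nan"), float(strength), False)
    diff = wrap_pm_pi(ev.mean_angle - ba.mean_angle)
    return PhaseLockIndices(diff, float(strength), True)


def individual_difference_correlations(
    table: pd.DataFrame,
    index_cols: list[str],
    predictor_cols: list[str],
    fdr: bool = True,
) -> pd.DataFrame:
    """Pearson correlations of coupling indices against participant-level
    physiological predictors (age, mean breath interval, breathing RMSSD,
    mean RR, HRV RMSSD); two-tailed p, optional BH-FDR column. A constant
    predictor yields a flagged NaN correlation."""
    if len(table) < 10:
        raise InsufficientDataError(
            "individual_difference_correlations needs >= 10 participants"
        )
    rows = []
    for ix in index_cols:
        for pred in predictor_cols:
            x = table[pred].to_numpy(dtype=float)
            y = table[ix].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            if ok.sum() < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                warnings.warn(f"correlation undefined for {ix} ~ {pred}", stacklevel=2)
                rows.append({"index": ix, "predictor": pred, "r": np.nan,
                             "p": np.nan, "n": int(ok.sum())})
                continue
            r, p = sstats.pearsonr(x[ok], y[ok])
            rows.append({"index": ix, "predictor": pred, "r": float(r),
                         "p": float(p), "n": int(ok.sum())})
    out = pd.DataFrame(rows)
    if fdr and out["p"].notna().any():
        adj = np.full(len(out), np.nan)
        mask = out["p"].notna().to_numpy()
        adj[mask] = fdr_adjust(out.loc[mask, "p"].to_numpy())
        out["p_fdr"] = adj
    return out
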
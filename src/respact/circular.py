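"""Circular inference: Hodges-Ajne omnibus statistic against circular-shift
surrogate nulls, the randomized Moore paired test, residualized circular
correlation with Fisher-z group inference, circular descriptives, and BH-FDR.

Why surrogates: exhalation lasts longer than inhalation, so even events
placed uniformly *in time* cluster in the exhalation half of the phase
circle. Testing the Hodges-Ajne M against surrogates obtained by circularly
time-shifting the phase series relative to the events preserves exactly that
duration structure in the null, so the test is calibrated despite the bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy import stats as sstats
from statsmodels.stats.multitest import multipletests

from .errors import AnalysisError, ConfigError, InsufficientDataError

TWO_PI = 2 * np.pi

# lookup signature used by the surrogate tests: times -> (phases, valid mask)
PhaseLookup = Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]]


@dataclass
class SurrogateTestResult:
    """Observed Hodges-Ajne statistic (per participant, or summed over the
    group), its surrogate distribution, and the two-tailed permutation p."""

    observed_m: int
    surrogate_ms: np.ndarray
    p_two_tailed: float
    n_surrogates: int
    seed: int | None = None


@dataclass(frozen=True)
class MooreResult:
    """Randomized Moore paired circular test outcome."""

    r_stat: float
    p: float
    n_pairs: int
    n_permutations: int


@dataclass(frozen=True)
class CircularSummary:
    mean_angle: float         # NaN when undefined (resultant ~ 0)
    resultant_length: float
    circ_variance: float      # 1 - resultant_length
    n: int
    defined: bool = True


# ---------------------------------------------------------------------------
# Hodges-Ajne omnibus statistic
# ---------------------------------------------------------------------------

def _m_from_sorted(theta: np.ndarray) -> int:
    """Exact minimum count over closed half-circles for sorted angles.

    The count over the closed arc [a, a + pi] is piecewise constant in a and
    changes only at the data angles and their antipodes; at those critical
    angles the closed arc gains boundary points, so the minimum is attained
    strictly between consecutive critical angles. Evaluating at the midpoints
    of those gaps is therefore exact.
    """
    n = theta.size
    crit = np.sort(np.concatenate([theta, np.mod(theta + np.pi, TWO_PI)]))
    gaps = np.diff(np.concatenate([crit, [crit[0] + TWO_PI]]))
    mids = np.mod(crit + gaps / 2, TWO_PI)
    ends = mids + np.pi
    # count of theta in [mid, mid+pi], handling the wrap past 2*pi
    lo = np.searchsorted(theta, mids, side="left")
    hi = np.searchsorted(theta, np.minimum(ends, TWO_PI), side="right")
    wrap_hi = np.searchsorted(theta, np.mod(ends, TWO_PI), side="right")
    counts = np.where(ends <= TWO_PI, hi - lo, (n - lo) + wrap_hi)
    return int(counts.min())


def hodges_ajne_m(phases: np.ndarray) -> int:
    """Hodges-Ajne M: the minimum number of sample angles contained in any
    closed half-circle. Small M indicates departure from circular uniformity;
    0 <= M <= floor(n/2)."""
    theta = np.mod(np.asarray(phases, dtype=float).ravel(), TWO_PI)
    if theta.size == 0:
        raise InsufficientDataError("hodges_ajne_m needs at least one angle")
    return _m_from_sorted(np.sort(theta))


# ---------------------------------------------------------------------------
# Circular-shift surrogate tests
# ---------------------------------------------------------------------------

def _two_tailed_p(observed: float, surrogates: np.ndarray) -> float:
    """Add-one two-tailed permutation p from a surrogate distribution."""
    n = surrogates.size
    lo = int(np.sum(surrogates <= observed)) + 1
    hi = int(np.sum(surrogates >= observed)) + 1
    return min(1.0, 2.0 * min(lo, hi) / (n + 1))


def _observed_m(event_times: np.ndarray, lookup: PhaseLookup, min_events: int) -> int:
    ph, ok = lookup(event_times)
    ph = ph[ok]
    if ph.size < min_events:
        raise InsufficientDataError(
            f"need at least {min_events} valid events, found {ph.size}"
        )
    return hodges_ajne_m(ph)


def group_surrogate_test(
    participants: Sequence[tuple[np.ndarray, PhaseLookup, tuple[float, float]]],
    n_surrogates: int = 1000,
    seed: int | None = None,
    min_events: int = 10,
) -> SurrogateTestResult:
    """Group-level omnibus test: observed statistic = sum of per-participant
    M values; each surrogate applies an independent circular time shift
    Delta ~ Uniform(0, span) to every participant's events, re-reads the
    phases, and re-sums. Two-tailed add-one permutation p.

    Each participant is a tuple (event_times, phase_lookup, (t_lo, t_hi)).
    """
    if len(participants) < 1:
        raise InsufficientDataError("need at least one participant")
    rng = np.random.default_rng(seed)
    obs = 0
    for times, lookup, _span in participants:
        obs += _observed_m(np.asarray(times, dtype=float), lookup, min_events)

    sur = np.zeros(n_surrogates, dtype=int)
    shifts = rng.uniform(0.0, 1.0, size=(n_surrogates, len(participants)))
    for j, (times, lookup, (t_lo, t_hi)) in enumerate(participants):
        times = np.asarray(times, dtype=float)
        span = t_hi - t_lo
        # all shifted event-time matrices at once, then one M per surrogate
        shifted = t_lo + np.mod(times[None, :] - t_lo + shifts[:, j : j + 1] * span, span)
        ph, ok = lookup(shifted.ravel())
        ph = ph.reshape(n_surrogates, -1)
        ok = ok.reshape(n_surrogates, -1)
        for s in range(n_surrogates):
            p_s = ph[s][ok[s]]
            sur[s] += _m_from_sorted(np.sort(np.mod(p_s, TWO_PI))) if p_s.size else 0
    p = _two_tailed_p(obs, sur)
    return SurrogateTestResult(int(obs), sur, p, n_surrogates, seed)


def surrogate_shift_test(
    event_times: np.ndarray,
    lookup: PhaseLookup,
    span: tuple[float, float],
    n_surrogates: int = 1000,
    seed: int | None = None,
    min_events: int = 10,
) -> SurrogateTestResult:
    """Single-participant circular-shift surrogate test (the group test with
    one participant, so the two agree exactly under a shared seed)."""
    return group_surrogate_test(
        [(event_times, lookup, span)], n_surrogates=n_surrogates, seed=seed,
        min_events=min_events,
    )


# ---------------------------------------------------------------------------
# Circular descriptives
# ---------------------------------------------------------------------------

def circ_mean(phases: np.ndarray) -> CircularSummary:
    """Circular mean direction and resultant length; the mean is flagged
    undefined when the resultant vanishes (e.g. antipodal pairs)."""
    th = np.asarray(phases, dtype=float).ravel()
    if th.size == 0:
        raise InsufficientDataError("circ_mean needs at least one angle")
    s, c = np.sum(np.sin(th)), np.sum(np.cos(th))
    r = float(np.hypot(s, c) / th.size)
    defined = r > 1e-12
    mean = float(np.mod(np.arctan2(s, c), TWO_PI)) if defined else float("nan")
    return CircularSummary(mean, r, 1.0 - r, th.size, defined)


def circ_variance(phases: np.ndarray) -> float:
    return circ_mean(phases).circ_variance


def wrap_pm_pi(angle: float) -> float:
    """Wrap an angle difference to (-pi, pi]."""
    return float(-np.mod(-angle + np.pi, TWO_PI) + np.pi)


# ---------------------------------------------------------------------------
# Randomized Moore paired circular test
# ---------------------------------------------------------------------------

def moores_paired_test(
    alpha: np.ndarray,
    beta: np.ndarray,
    n_permutations: int = 10000,
    seed: int | None = None,
) -> MooreResult:
    """Rank-based paired test for a consistent angular difference.

    Each pair contributes the difference vector d_i = (cos a_i - cos b_i,
    sin a_i - sin b_i); nonzero vectors are ranked by magnitude (average
    ranks on ties) and the statistic is
    R = |sum_i R_i (cos phi_i, sin phi_i)| / n^{3/2} with phi_i the vector's
    angle. The null randomizes the sign of each difference vector (the
    natural exchangeability under no consistent difference);
    p = (#{R_perm >= R_obs} + 1)/(N + 1).
    """
    a = np.asarray(alpha, dtype=float).ravel()
    b = np.asarray(beta, dtype=float).ravel()
    if a.size != b.size:
        raise ConfigError("alpha and beta must be paired (equal length)")
    if a.size < 5:
        raise InsufficientDataError("moores_paired_test needs at least 5 pairs")
    dx = np.cos(a) - np.cos(b)
    dy = np.sin(a) - np.sin(b)
    mag = np.hypot(dx, dy)
    nz = mag > 1e-12
    n = int(nz.sum())
    if n == 0:
        warnings.warn("all paired difference vectors are zero; p = 1", stacklevel=2)
        return MooreResult(0.0, 1.0, 0, n_permutations)
    ranks = sstats.rankdata(mag[nz])
    phi = np.arctan2(dy[nz], dx[nz])
    x = ranks * np.cos(phi)
    y = ranks * np.sin(phi)
    scale = n ** 1.5
    r_obs = float(np.hypot(x.sum(), y.sum()) / scale)

    rng = np.random.default_rng(seed)
    # sign flip negates the vector: phi -> phi + pi, rank unchanged
    count = 0
    chunk = max(1, min(n_permutations, int(4e6 // max(n, 1))))
    done = 0
    while done < n_permutations:
        m = min(chunk, n_permutations - done)
        signs = rng.integers(0, 2, size=(m, n)) * 2 - 1
        r_perm = np.hypot(signs @ x, signs @ y) / scale
        count += int(np.sum(r_perm >= r_obs))
        done += m
    p = (count + 1) / (n_permutations + 1)
    return MooreResult(r_obs, float(p), n, n_permutations)


# ---------------------------------------------------------------------------
# Residualized circular correlation
# ---------------------------------------------------------------------------

def residualize_phase(phases: np.ndarray, covariate: np.ndarray) -> np.ndarray:
    """Remove the linear effect of a covariate from a phase sample.

    Each angle is decomposed into sine and cosine components, the covariate's
    linear effect is removed from each component by OLS (with intercept), and
    the residual pairs are recombined with the two-argument arctangent. A
    constant covariate degenerates to centering the components, which leaves
    every angle's direction information intact.
    """
    th = np.asarray(phases, dtype=float).ravel()
    c = np.asarray(covariate, dtype=float).ravel()
    if th.size != c.size:
        raise ConfigError("phases and covariate must have equal length")
    if th.size < 5:
        raise InsufficientDataError("residualize_phase needs at least 5 events")
    if not np.all(np.isfinite(c)):
        raise ConfigError("covariate must be finite")
    X = np.column_stack([np.ones_like(c), c])
    res = np.empty((th.size, 2))
    for k, comp in enumerate((np.sin(th), np.cos(th))):
        coef, *_ = np.linalg.lstsq(X, comp, rcond=None)
        res[:, k] = comp - X @ coef
    return np.mod(np.arctan2(res[:, 0], res[:, 1]), TWO_PI)


def circ_corr(alpha: np.ndarray, beta: np.ndarray) -> float:
    """Jammalamadaka-SenGupta circular correlation coefficient."""
    a = np.asarray(alpha, dtype=float).ravel()
    b = np.asarray(beta, dtype=float).ravel()
    if a.size != b.size or a.size < 5:
        raise InsufficientDataError("circ_corr needs >= 5 paired angles")
    ma, mb = circ_mean(a), circ_mean(b)
    if not (ma.defined and mb.defined):
        raise AnalysisError("circular correlation undefined: a mean direction vanishes")
    sa = np.sin(a - ma.mean_angle)
    sb = np.sin(b - mb.mean_angle)
    denom = np.sqrt(np.sum(sa ** 2) * np.sum(sb ** 2))
    if denom == 0:
        raise AnalysisError("circular correlation undefined: zero denominator")
    return float(np.sum(sa * sb) / denom)


def fisher_z(r: float) -> float:
    """Fisher's variance-stabilizing transform z = atanh(r)."""
    if abs(r) >= 1:
        raise AnalysisError("Fisher z is infinite at |r| = 1")
    return float(np.arctanh(r))


@dataclass(frozen=True)
class GroupTResult:
    t: float
    p: float
    cohen_d: float
    n: int
    defined: bool = True


def group_t(z_values: np.ndarray, mu0: float = 0.0) -> GroupTResult:
    """One-sample t-test on per-participant Fisher z values, with Cohen's
    d = mean/SD. Zero-variance input is flagged undefined."""
    z = np.asarray(z_values, dtype=float).ravel()
    if z.size < 2:
        raise InsufficientDataError("group_t needs at least 2 participants")
    sd = float(np.std(z, ddof=1))
    if sd == 0:
        return GroupTResult(float("nan"), float("nan"), float("nan"), z.size, False)
    t, p = sstats.ttest_1samp(z, mu0)
    d = float((z.mean() - mu0) / sd)
    return GroupTResult(float(t), float(p), d, z.size)


def fdr_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float).ravel()
    if p.size == 0:
        return p
    if np.any(~np.isfinite(p)) or np.any((p < 0) | (p > 1)):
        raise ConfigError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
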
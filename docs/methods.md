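# Methods

`respact` asks a simple question with awkward statistics: do self-initiated
actions (a key press at a freely chosen moment, a spontaneous joystick
movement) and the stimuli that precede them occur at preferred phases of the
respiratory and cardiac cycles? The statistics are awkward because the two
halves of a breath are not the same length — exhalation outlasts inhalation —
so even behavior completely blind to breathing piles up in the exhalation
half of the phase circle. Everything in this package is organized around
measuring phase coupling in a way that is immune to that bias, and around
being able to *prove* the immunity on simulated data whose ground truth is
known exactly.

## Phase conventions

Respiratory phase lives in [0, 2π): troughs of the (belt-aligned)
respiration signal are 0 and 2π, peaks are π, inhalation is [0, π),
exhalation [π, 2π). Cardiac phase is linear between consecutive R-peaks,
2π·(t − R_prev)/(R_next − R_prev), with the R-peak at 0. The systolic window
is 200–400 ms after each R-peak.

## The synthetic generator (`synth`)

The generator is first-class code, not a test fixture: it defines the
conditions under which every downstream claim is verified.

- **Breath cycles.** Inhale and exhale durations are drawn independently per
  cycle from Gamma distributions matched to mean/SD (Gamma because the
  support must be positive and only mean and SD are specified). Defaults:
  inhale 1.781 s (SD 0.422), exhale 2.173 s (SD 0.603), i.e. an exhalation
  time fraction near 0.55 — the bias the inference must survive. The belt
  waveform is a chain of half-cosines (−1 at troughs, +1 at peaks); the true
  phase is piecewise linear in time, 0→π over the inhale and π→2π over the
  exhale, wrapping exactly at troughs.
- **Thermal airflow channel.** The airflow trace is the belt waveform passed
  through a mild saturating nonlinearity (tanh, which flattens extrema the
  way a flow signal plateaus but moves neither extrema nor zero crossings),
  sign-inverted, delayed by 382.5 ms (77 samples at 200 Hz, half-up
  rounding), plus white noise. Modelling the channel as a delayed inverted
  copy rather than a literal time-derivative keeps the configured delay
  identifiable by cross-correlation, which is how the preprocessing (and the
  recovery check) estimates it.
- **ECG.** R-R intervals follow a positive AR(1) Gaussian (mean 0.800 s,
  marginal SD 0.100 s, lag-one coefficient 0.4 — the autocorrelation value
  is a free parameter with a documented default). The trace is a fixed
  QRS-T-like template superposed at each R time plus noise; morphology
  beyond detectability is a non-goal.
- **Behavioral sessions.** Libet-style trials: dot onset, a self-chosen
  action after a waiting time drawn from a lognormal with median 4 s
  (log-SD 0.35; right-skewed waits are physiologically typical) truncated
  below at one dot rotation (2.56 s), then a 4–8 s inter-trial interval.
  The key-release condition adds an initial press at onset + N(0.414 s,
  0.105 s). Elbow sessions pace one action every 8–12 s and render a
  joystick pulse per action, timed so its ±0.40 threshold crossing lands on
  the action time (the first sample beyond threshold is recorded, making
  detector accuracy exactly measurable).
- **Phase coupling.** Three placement modes. `uniform_time` uses the drawn
  waiting times as-is (the null; events then hit exhalation in proportion to
  its duration). `uniform_phase` and `von_mises` draw a target phase
  (uniform, or von Mises(μ, κ)) and relocate the action to the first moment
  at or after its minimum wait at which the true phase crosses the target —
  solved exactly on the piecewise-linear phase, so event times stay causally
  ordered and the configured pacing is approximately preserved. κ = 0 in von
  Mises mode draws uniform targets and is distributionally identical to
  `uniform_phase`. Note that uniform-*phase* placement is **not** a null for
  the surrogate test below: events uniform in phase are non-uniform in time
  (they under-represent exhalation relative to its duration), and the test
  correctly flags that. The calibration study therefore treats "κ = 0" as
  uniform-in-time placement.
- **Anomalies.** With configurable per-cycle probabilities the generator
  inserts end-expiratory pauses (the waveform holds the trough value for an
  Exponential extra time appended to the exhale) and abnormally long cycles
  (durations scaled ×4). Both are flagged in the ground truth so the IQR
  fence's recall can be scored.

What the generator does *not* emulate: drifting baselines and motion
artifacts in the belt, ectopic beats and electrode noise beyond white noise,
respiratory-cardiac interaction (no sinus arrhythmia), learning or fatigue
trends in behavior. Passing tests therefore demonstrate the statistical
machinery, not robustness to every artifact of real recordings.

## Preprocessing (`preprocess`)

Band-pass filters are 4th-order Butterworth applied forward-backward
(`sosfiltfilt`); the band edges are 0.1–3 Hz for respiration and 0.5–40 Hz
for ECG. Zero-phase filtering is chosen because instantaneous phase is the
analysis target; a causal pass would shift it.

Airflow alignment inverts the thermal signal and searches integer-sample
lags in [0, 2 s] (the thermal delay is physically positive and sub-second)
for the maximum Pearson correlation with the belt, advancing the airflow by
the best lag.

Respiratory phase: the Hilbert-transform angle of the negated aligned
airflow segments the record at its wraps (approximate troughs). Because the
breath waveform is asymmetric, the raw analytic angle drifts systematically
near extrema (≈0.17 rad for the default asymmetry, enough to misclassify
~6% of samples), so the phase is anchored: troughs and peaks are refined to
the waveform extrema (±0.35 s search around each wrap) and the phase is
linear in time within each half-cycle. This realizes the stated convention
(trough = 0, peak = π) exactly and keeps the per-sample inhale/exhale
classification above 95% against ground truth on clean data.

Outlier fencing: a respiratory cycle is flagged if *any* of its total,
inhale, or exhale duration falls outside [Q1 − 2.5·IQR, Q3 + 2.5·IQR],
fences computed per duration type over the participant's own cycles
(quartiles by linear interpolation, Hyndman–Fan 7). R-R intervals use the
same construction with k = 2.0. Flags are set, nothing is deleted, and the
operation is idempotent because fences always use all cycles. Events falling
in flagged cycles/intervals are marked invalid and excluded from phase
analyses. Respiratory pauses stay inside their host cycle by default; the
generator can flag them for sensitivity analyses.

R-peaks: derivative → squaring → 150 ms moving-average integration,
candidates above an adaptive threshold with a 250 ms refractory period, each
refined to the local ECG maximum (±80 ms).

Event phases are read at the nearest sample (at 200 Hz the half-sample error
is 2.5 ms, negligible against breath cycles of ~4 s).

## Inference (`circular`)

**Hodges–Ajne M** is the minimum number of sample angles in any closed
half-circle; small M means non-uniformity. The count over closed arcs
[a, a + π] changes only at data angles and their antipodes and its minimum
is attained strictly between consecutive critical angles, so evaluating at
gap midpoints is exact. Tests cross-check against an independent brute-force
enumeration. (A fixed-resolution orientation grid is *not* an exact oracle:
the minimizing gap can be narrower than the grid step.)

**Circular-shift surrogates.** The null distribution of M is built by
drawing Δ ~ Uniform(0, span) and re-reading phases at (t + Δ) mod span —
equivalently, rotating the whole phase record relative to the events. This
preserves the phase-duration structure (including the exhalation bias and
any cycle exclusions), which is exactly why the test is calibrated where a
textbook uniformity test is not. The group statistic sums per-participant M
values; each surrogate shifts every participant independently. The
two-tailed p is `min(1, 2·min(#{M_s ≤ M_obs}+1, #{M_s ≥ M_obs}+1)/(N+1))`
(add-one smoothing; with heavy ties on an integer statistic this is
conservative, which the calibration study quantifies). Defaults: 1000
surrogates per test.

**Moore's paired test, randomized.** Per pair, the Cartesian difference
vector d_i = (cos α_i − cos β_i, sin α_i − sin β_i); nonzero vectors ranked
by magnitude (average ranks on ties; zero vectors dropped with n reduced),
statistic R = |Σ R_i(cos φ_i, sin φ_i)|/n^{3/2}. The permutation null
negates each d_i independently with probability ½ (equivalent to swapping
the pair's labels); p = (#{R_perm ≥ R_obs} + 1)/(N + 1), default N = 10,000.
A property worth knowing: the statistic tests for a common *vector*
difference, so a pure rotation of a perfectly uniform sample is invisible
(the d_i then point uniformly in all directions); power against rotations
requires a dispersed-but-concentrated sample, and the validation suite
demonstrates both facts.

**Residualized circular correlation.** To control an interval confound,
each phase is decomposed into sine and cosine components, the covariate's
linear effect removed from each by OLS with intercept, and the residual
pairs recombined by atan2. Correlations are Jammalamadaka–SenGupta
(sin-deviation products), Fisher-z transformed per participant, and tested
at the group level with a one-sample t (Cohen's d = mean/SD). The
confound-removal study drives both stimulus and action mean phases linearly
by the inter-event interval plus independent von Mises noise; the noise is
essential to the construction — with strictly deterministic phases the two
residual series would still be functions of the same covariate and no
correlation measure could certify removal. Linear-in-interval drift is also
the component the method claims to remove; curvature beyond the linear term
is deliberately small over the interval range used.

**FDR** is Benjamini–Hochberg step-up (via statsmodels), applied within
analysis families (circular tests per task and signal; state t-tests per
measure), never globally. Adjusted values are monotone and capped at 1;
note BH adjustment is *not* idempotent in adjusted values, so adjusted
p-values are never re-adjusted.

## State analyses (`states`)

The exhalation ratio (fraction of events with phase in [π, 2π)) is compared
to the participant's *temporal* baseline Σt_ex/Σt_total over valid cycles;
the systole ratio (fraction of events 200–400 ms post-R) to the
time-weighted window proportion, where an interval shorter than 400 ms
contributes only its truncated overlap (an unweighted per-interval mean is
provided as a secondary variant). Inhalation and non-systole ratios are
complements and not analyzed separately. Group inference: paired t against
baseline (d = mean difference/SD of differences) and a two-way
within-subject ANOVA (condition × timing) computed by the balanced
sum-of-squares decomposition, each effect tested against its own
subject-by-effect interaction; generalized eta squared is
SS_effect/(SS_effect + SS_subjects + ΣSS_error). The implementation is
cross-checked against an independent least-squares implementation to 1e-6.

Peri-event breathing intervals take the durations of the cycle before,
containing, and after each event ("during" = the cycle containing the
event); edge events and events with flagged neighbors are excluded from the
triplet analysis.

Phase-locking indices per participant × condition: phase difference =
circular mean of event phases minus circular mean of the baseline phase
sample, wrapped to (−π, π]; locking strength = baseline circular variance
minus event circular variance (positive = events more concentrated than the
recording). The baseline sample is all valid phase samples of the recording
(dense sampling mirrors the temporal-proportion logic); variability is
circular variance 1 − R̄. Undefined circular means (vanishing resultant)
propagate as flagged values, never silent zeros.

## Orchestration and validation (`pipeline`, `cli`)

`run_study` composes the full chain per participant and condition —
simulate (or read), preprocess, filter, attach phases, test — and writes
tidy CSV tables plus a JSON manifest (config, seed, version, stage log).
One master seed is expanded into per-stage substreams so toggling one
analysis never perturbs another's randomness; identical configs reproduce
identical tables. Libet participants with fewer than 20 valid trials in
either condition are excluded from that task's analyses (the elbow task has
no such threshold).

The Monte-Carlo studies simulate at the cycle-table level (exact analytic
phase, no signal rendering): they calibrate the *statistic*, while the
signal path is validated separately by the phase-recovery checks. Problem
sizes used by the validation suite: 200 replicate null studies of 8
participants × 40 events with 200 surrogates for type-I error; 100
replicates × 28 participants × 40 events at κ ∈ {0, 0.5, 1, 2} (μ = 7π/4)
for power; 500 replicates for Moore calibration; 20 participants × 200
events for confound removal.

## Known limitations

- The anchored-phase construction assumes one dominant extremum pair per
  cycle; bi-phasic breaths or long pauses blur the trough location (pauses
  are generator-flaggable for exactly this reason).
- The surrogate test conditions on the realized phase record; very short
  recordings (few cycles) make the shift null coarse.
- Moore's test cannot see pure rotations of uniform samples (above).
- Cohen's d and the rmANOVA assume the usual normality of participant-level
  summaries; no small-sample corrections are applied.
- Bayes factors and mixed-effects robustness models are out of scope.
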
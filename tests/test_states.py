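"""State-ratio, peri-event, rmANOVA, and individual-difference tests."""

import numpy as np
import pandas as pd
import pytest

import respact as ra
from respact.states import (
    PairedTResult,
    baseline_systole_ratio_per_interval,
    paired_t_vs_baseline,
)


def _cycles(totals, t_in_frac=0.45):
    totals = np.asarray(totals, dtype=float)
    t_in = totals * t_in_frac
    trough = np.concatenate([[0], np.cumsum(totals)[:-1]])
    return pd.DataFrame({
        "trough_time": trough, "peak_time": trough + t_in,
        "next_trough_time": trough + totals, "t_in": t_in,
        "t_ex": totals - t_in, "t_total": totals,
        "excluded": False, "exclusion_reason": "none",
    })


class TestExhalationRatio:
    def test_all_exhalation_events(self):
        assert ra.exhalation_ratio(np.full(10, 3 * np.pi / 2)) == 1.0

    def test_baseline_from_durations(self):
        cycles = _cycles([4.0] * 10, t_in_frac=1.5 / 4.0)
        assert ra.baseline_exhalation_ratio(cycles) == pytest.approx(0.625)

    def test_complementarity(self):
        rng = np.random.default_rng(0)
        ph = rng.uniform(0, 2 * np.pi, 500)
        ex = ra.exhalation_ratio(ph)
        inh = np.mean(ph < np.pi)
        assert ex + inh == pytest.approx(1.0)

    def test_uniform_time_events_converge_to_baseline(self):
        phases, t_ex, t_tot = [], 0.0, 0.0
        for s in range(10):
            c = ra.SimConfig(seed=600 + s, duration=210 * 24 + 60)
            tr = ra.simulate_truth_only(c)
            ev = ra.simulate_libet_session(c, tr, "key_press", 210)
            phases.append(ev.loc[ev.event_type == "key_press", "true_phase"].to_numpy())
            t_ex += tr.cycle_table["t_ex"].sum()
            t_tot += tr.cycle_table["t_total"].sum()
        ph = np.concatenate(phases)
        assert ph.size >= 2000
        assert abs(ra.exhalation_ratio(ph) - t_ex / t_tot) < 0.02

    def test_no_events_flagged(self):
        with pytest.warns(UserWarning):
            assert np.isnan(ra.exhalation_ratio([]))


class TestSystoleRatio:
    def test_constant_rr_baseline(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.arange(20) * 0.8,
                                  rr=np.full(19, 0.8))
        assert ra.baseline_systole_ratio(cc) == pytest.approx(0.25)

    def test_event_in_window_counted(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.arange(10) * 0.8,
                                  rr=np.full(9, 0.8))
        assert ra.systole_ratio(np.array([1.6 + 0.3]), cc) == 1.0
        assert ra.systole_ratio(np.array([1.6 + 0.1]), cc) == 0.0

    def test_short_interval_window_truncated(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.array([0.0, 0.35]),
                                  rr=np.array([0.35]))
        # overlap of [0.2, 0.4] with [0, 0.35] is 0.15 s
        assert ra.baseline_systole_ratio(cc) == pytest.approx(0.15 / 0.35)

    def test_excluded_interval_events_dropped(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.array([0.0, 0.8, 1.6, 2.4]),
                                  rr=np.full(3, 0.8),
                                  excluded=np.array([False, True, False]))
        with pytest.warns(UserWarning):
            out = ra.systole_ratio(np.array([1.1]), cc)  # only event is excluded
        assert np.isnan(out)

    def test_per_interval_variant(self):
        cc = ra.CardiacCycleTable(rpeak_times=np.array([0.0, 0.8, 1.2]),
                                  rr=np.array([0.8, 0.4]))
        # time-weighted: (0.2 + 0.2) / 1.2; per-interval: mean(0.25, 0.5)
        assert ra.baseline_systole_ratio(cc) == pytest.approx(0.4 / 1.2)
        assert baseline_systole_ratio_per_interval(cc) == pytest.approx(0.375)

    def test_uniform_time_events_converge_to_baseline(self):
        rng = np.random.default_rng(9)
        rr = rng.normal(0.8, 0.05, 4000)
        peaks = np.concatenate([[0.0], np.cumsum(rr)])
        cc = ra.CardiacCycleTable(rpeak_times=peaks)
        events = rng.uniform(0, peaks[-1], 3000)
        assert abs(ra.systole_ratio(events, cc)
                   - ra.baseline_systole_ratio(cc)) < 0.02


class TestPeriEvent:
    def test_constant_cycles_triplet(self):
        cycles = _cycles([4.0] * 10)
        out = ra.peri_event_breathing_intervals(np.array([18.0]), cycles)
        assert out.loc[0, ["before1", "during", "after1"]].tolist() == [4.0, 4.0, 4.0]

    def test_stretched_host_cycle_recovered(self):
        totals = [4.0] * 10
        totals[5] = 4.5
        cycles = _cycles(totals)
        t_evt = cycles.loc[5, "trough_time"] + 1.0
        out = ra.peri_event_breathing_intervals(np.array([t_evt]), cycles)
        assert out.loc[0, "during"] - out.loc[0, "before1"] == pytest.approx(0.5)

    def test_edge_event_flagged(self):
        cycles = _cycles([4.0] * 5)
        out = ra.peri_event_breathing_intervals(np.array([1.0]), cycles)
        assert not bool(out.loc[0, "valid"])


class TestGroupTests:
    def test_values_equal_baselines(self):
        res = paired_t_vs_baseline(np.full(6, 0.55), np.full(6, 0.55))
        assert isinstance(res, PairedTResult)
        assert res.t == 0.0 and not res.defined

    def test_paired_t_matches_scipy(self):
        rng = np.random.default_rng(1)
        v = rng.normal(0.6, 0.05, 12)
        b = rng.normal(0.55, 0.05, 12)
        res = paired_t_vs_baseline(v, b)
        from scipy import stats
        t, p = stats.ttest_rel(v, b)
        assert res.t == pytest.approx(t)
        assert res.p == pytest.approx(p)
        d = v - b
        assert res.cohen_d == pytest.approx(d.mean() / d.std(ddof=1))

    def _anova_frame(self, rng, n_s=6, timing_effect=0.0, cond_effect=0.0):
        rows = []
        for s in range(n_s):
            base = rng.normal(0.5, 0.05)
            for ci, cond in enumerate(["a", "b"]):
                for ti, timing in enumerate(["t1", "t2"]):
                    rows.append({
                        "participant": s, "condition": cond, "timing": timing,
                        "value": base + ci * cond_effect + ti * timing_effect
                                 + rng.normal(0, 0.02),
                    })
        return pd.DataFrame(rows)

    def test_timing_only_effect_pattern(self):
        rng = np.random.default_rng(2)
        df = self._anova_frame(rng, n_s=10, timing_effect=0.2)
        out = ra.rm_anova_2way(df).set_index("effect")
        assert out.loc["timing", "F"] > 50
        assert out.loc["condition", "F"] < 10
        assert out.loc["timing", "p"] < 1e-4

    def test_matches_pingouin_oracle(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = self._anova_frame(rng, n_s=5, timing_effect=0.05, cond_effect=0.03)
        ours = ra.rm_anova_2way(df).set_index("effect")
        theirs = pg.rm_anova(data=df, dv="value", within=["condition", "timing"],
                             subject="participant", detailed=True)
        for eff, key in (("condition", "condition"), ("timing", "timing"),
                         ("condition:timing", "condition * timing")):
            row = theirs[theirs["Source"].str.lower() == key.lower()].iloc[0]
            assert ours.loc[eff, "F"] == pytest.approx(row["F"], abs=1e-6)
            assert ours.loc[eff, "p"] == pytest.approx(row["p_unc"], abs=1e-6)
            if "ng2" in theirs.columns:
                assert ours.loc[eff, "ges"] == pytest.approx(row["ng2"], abs=1e-6)

    def test_order_invariance(self):
        rng = np.random.default_rng(4)
        df = self._anova_frame(rng, n_s=6, timing_effect=0.1)
        shuffled = df.sample(frac=1.0, random_state=0)
        pd.testing.assert_frame_equal(
            ra.rm_anova_2way(df), ra.rm_anova_2way(shuffled)
        )


class TestPhaseLockIndices:
    def test_identical_event_phases_maximal(self):
        rng = np.random.default_rng(5)
        baseline = rng.uniform(0, 2 * np.pi, 2000)
        out = ra.phase_lock_indices(np.full(50, 1.0), baseline)
        bvar = ra.circ_mean(baseline).circ_variance
        assert out.locking_strength == pytest.approx(bvar, abs=1e-9)

    def test_null_strength_near_zero(self):
        rng = np.random.default_rng(6)
        baseline = rng.vonmises(2.0, 0.8, 5000) % (2 * np.pi)
        events = rng.choice(baseline, 800, replace=False)
        out = ra.phase_lock_indices(events, baseline)
        assert abs(out.locking_strength) < 0.05

    def test_phase_difference_recovery(self):
        cfg = ra.SimConfig(seed=62, duration=2000,
                           coupling_mode="von_mises", kappa=2.0, mu=7 * np.pi / 4)
        truth = ra.simulate_truth_only(cfg)
        ev, _ = ra.simulate_elbow_session(cfg, truth, "push", 150)
        events = ev["true_phase"].to_numpy()
        tgrid = np.arange(truth.span[0], truth.span[1], 0.01)
        baseline = truth.phase_at(tgrid)
        baseline = baseline[np.isfinite(baseline)]
        out = ra.phase_lock_indices(events, baseline)
        expected = ra.circ_mean(baseline)
        want = np.angle(np.exp(1j * (7 * np.pi / 4 - expected.mean_angle)))
        assert abs(np.angle(np.exp(1j * (out.phase_difference - want)))) < 0.15
        assert out.locking_strength > 0


class TestIndividualDifferences:
    def _table(self, rng, n=20, slope=0.0, noise=0.05):
        rmssd = rng.uniform(0.1, 0.6, n)
        lock = 0.1 + slope * rmssd + rng.normal(0, noise, n)
        return pd.DataFrame({
            "participant": np.arange(n), "breathing_rmssd": rmssd,
            "locking_strength": lock, "age": rng.uniform(20, 45, n),
        })

    def test_exact_predictor_r_one(self):
        rng = np.random.default_rng(7)
        tab = self._table(rng)
        tab["self"] = tab["locking_strength"]
        out = ra.individual_difference_correlations(tab, ["locking_strength"], ["self"])
        assert out["r"].iloc[0] == pytest.approx(1.0)

    def test_linear_dependence_recovered(self):
        hits = 0
        for s in range(20):
            rng = np.random.default_rng(700 + s)
            tab = self._table(rng, slope=0.4, noise=0.03)
            out = ra.individual_difference_correlations(
                tab, ["locking_strength"], ["breathing_rmssd"])
            hits += out["r"].iloc[0] > 0
        assert hits >= 19

    def test_constant_predictor_flagged(self):
        rng = np.random.default_rng(8)
        tab = self._table(rng)
        tab["flat"] = 1.0
        with pytest.warns(UserWarning):
            out = ra.individual_difference_correlations(
                tab, ["locking_strength"], ["flat"])
        assert np.isnan(out["r"].iloc[0])

    def test_too_few_participants(self):
        rng = np.random.default_rng(9)
        with pytest.raises(ra.InsufficientDataError):
            ra.individual_difference_correlations(
                self._table(rng, n=5), ["locking_strength"], ["age"])
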
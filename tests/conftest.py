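import numpy as np
import pytest

import respact as ra


@pytest.fixture(scope="session")
def clean_recording():
    """A 300 s noise-free recording with ground truth, preprocessed once."""
    cfg = ra.SimConfig(seed=1, duration=300.0, airflow_noise_sd=0.0)
    belt, airflow, truth = ra.simulate_respiration(cfg)
    ecg, rpeaks = ra.simulate_cardiac(cfg)
    truth.rpeak_times = rpeaks
    series, cycles, cardiac, alignment = ra.preprocess_recording(belt, airflow, ecg)
    return {
        "config": cfg, "belt": belt, "airflow": airflow, "ecg": ecg,
        "truth": truth, "series": series, "cycles": cycles,
        "cardiac": cardiac, "alignment": alignment,
    }


@pytest.fixture(scope="session")
def noisy_recording():
    """Default-noise 300 s recording, preprocessed once."""
    cfg = ra.SimConfig(seed=2, duration=300.0)
    belt, airflow, truth = ra.simulate_respiration(cfg)
    ecg, rpeaks = ra.simulate_cardiac(cfg)
    truth.rpeak_times = rpeaks
    series, cycles, cardiac, alignment = ra.preprocess_recording(belt, airflow, ecg)
    return {
        "config": cfg, "truth": truth, "series": series, "cycles": cycles,
        "cardiac": cardiac, "alignment": alignment,
    }


def oracle_hodges_ajne(phases):
    """Independent brute-force oracle: direct count of points in the closed
    half-circle [a, a + pi] for every candidate orientation at which the
    count can change (each data angle, its antipode, and a point just past
    each). Exact for continuous data; a fixed-resolution orientation grid is
    not, because the minimizing interval between consecutive candidate
    angles can be arbitrarily narrow."""
    th = np.mod(np.asarray(phases, dtype=float), 2 * np.pi)
    eps = 1e-9
    cands = np.mod(np.concatenate([th, th + np.pi, th + eps, th + np.pi + eps]),
                   2 * np.pi)
    best = th.size
    for a in cands:
        rel = np.mod(th - a, 2 * np.pi)
        best = min(best, int(np.sum(rel <= np.pi + 1e-12)))
    return best
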
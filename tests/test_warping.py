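"""DTW alignment, path transfer, and the warp-normalized contrast."""

import itertools

import numpy as np
import pytest

import daf_ecog as de
from daf_ecog.exceptions import WarpingError
from daf_ecog.synth import generate_stretch_cohort
from daf_ecog.warping import warped_paired_contrast


def brute_force_dtw_cost(a, b):
    """Independent oracle: explicit enumeration of every monotone boundary
    path with steps {(1,0),(0,1),(1,1)}, minimizing absolute-difference cost."""
    n, m = len(a), len(b)
    best = [np.inf]

    def walk(i, j, acc):
        acc = acc + abs(a[i] - b[j])
        if acc >= best[0]:
            return
        if i == n - 1 and j == m - 1:
            best[0] = acc
            return
        if i + 1 < n and j + 1 < m:
            walk(i + 1, j + 1, acc)
        if i + 1 < n:
            walk(i + 1, j, acc)
        if j + 1 < m:
            walk(i, j + 1, acc)

    walk(0, 0, 0.0)
    return best[0]


def test_dtw_identical_sequences_pure_diagonal_zero_cost():
    a = np.array([0.2, 0.5, 1.0, 0.3])
    p = de.dtw_align(a, a)
    assert p.cost == 0.0
    np.testing.assert_array_equal(p.pairs, np.c_[np.arange(4), np.arange(4)])


def test_dtw_worked_example():
    p = de.dtw_align([0.0, 1.0, 2.0], [0.0, 1.0, 1.0, 2.0])
    assert p.cost == 0.0
    assert p.pairs.tolist() == [[0, 0], [1, 1], [1, 2], [2, 3]]


def test_dtw_path_structure_invariants():
    rng = np.random.default_rng(0)
    for _ in range(20):
        a = rng.uniform(size=rng.integers(2, 12))
        b = rng.uniform(size=rng.integers(2, 12))
        p = de.dtw_align(a, b)
        assert tuple(p.pairs[0]) == (0, 0)
        assert tuple(p.pairs[-1]) == (len(a) - 1, len(b) - 1)
        steps = np.diff(p.pairs, axis=0)
        assert set(map(tuple, steps)) <= {(1, 0), (0, 1), (1, 1)}
        assert p.cost >= 0


def test_dtw_matches_exhaustive_oracle_small():
    rng = np.random.default_rng(1)
    for _ in range(40):
        a = rng.uniform(size=rng.integers(1, 9))
        b = rng.uniform(size=rng.integers(1, 9))
        assert de.dtw_align(a, b).cost == pytest.approx(brute_force_dtw_cost(a, b), abs=1e-12)


def test_dtw_cost_symmetry():
    rng = np.random.default_rng(2)
    for _ in range(20):
        a = rng.uniform(size=7)
        b = rng.uniform(size=11)
        assert de.dtw_align(a, b).cost == pytest.approx(de.dtw_align(b, a).cost, abs=1e-12)


def test_apply_warp_identity_and_mean_rule():
    p = de.dtw_align([0.0, 1.0, 2.0], [0.0, 1.0, 2.0])
    x = np.array([10.0, 20.0, 30.0])
    np.testing.assert_array_equal(de.apply_warp(p, x), x)
    p2 = de.dtw_align([0.0, 1.0, 2.0], [0.0, 1.0, 1.0, 2.0])
    out = de.apply_warp(p2, np.array([10.0, 20.0, 30.0, 40.0]))
    np.testing.assert_allclose(out, [10.0, 25.0, 40.0])  # bin 1 = mean(20, 30)
    with pytest.raises(WarpingError):
        de.apply_warp(p2, np.ones(7))


def test_apply_warp_preserves_path_weighted_average():
    rng = np.random.default_rng(3)
    a, b = rng.uniform(size=30), rng.uniform(size=40)
    p = de.dtw_align(a, b)
    x = rng.normal(size=40)
    out = de.apply_warp(p, x)
    expected_total = sum(np.mean(x[js]) for js in p.target_bins_for_source())
    assert out.sum() == pytest.approx(expected_total, rel=1e-12)


def test_warp_recovers_time_stretched_response():
    """A 1.25x time-stretched response warped by the path from its own
    envelope pair comes back close to the unstretched response."""
    c = generate_stretch_cohort(n_stimuli=1, n_trials_per_cell=1, stretch=1.25,
                                noise_sd=0.0, seed=5)
    s = c["stimuli"][0]
    path = de.dtw_align(c["env0"][s], c["env200"][s])
    warped = de.apply_warp(path, c["series"][(s, 200)][0])
    ref = c["series"][(s, 0)][0]
    rms = np.sqrt(np.mean((warped - ref) ** 2))
    assert rms < 0.05 * ref.max()


# ------------------------------------------------------- speech envelopes --

def test_speech_envelope_constant_tone_is_flat():
    import pandas as pd
    fs = 512.0
    t = np.arange(int(6 * fs)) / fs
    audio = np.sin(2 * np.pi * 80 * t)
    trials = pd.DataFrame({"trial": [0], "stimulus_id": ["s00"], "delay_ms": [0],
                           "speech_onset_s": [1.0], "duration_s": [3.0]})
    env = de.speech_envelope(audio, fs, trials, "s00", 0)
    e = env.envelope
    assert e.std() / e.mean() < 0.10  # flat up to spectrogram windowing ripple


def test_speech_envelope_square_modulated_tone_alternates():
    import pandas as pd
    fs = 512.0
    t = np.arange(int(6 * fs)) / fs
    mod = (np.sin(2 * np.pi * 2.0 * t) > 0).astype(float)  # 250-ms blocks
    audio = mod * np.sin(2 * np.pi * 80 * t)
    trials = pd.DataFrame({"trial": [0], "stimulus_id": ["s00"], "delay_ms": [0],
                           "speech_onset_s": [1.0], "duration_s": [2.0]})
    env = de.speech_envelope(audio, fs, trials, "s00", 0).envelope
    grid = 0.01 * np.arange(env.size)
    # compare envelope means in on- vs off-blocks (away from transitions)
    phase = (grid + 1.0) % 0.5
    on = (phase > 0.06) & (phase < 0.19)
    off = (phase > 0.31) & (phase < 0.44)
    assert env[on].mean() > 3 * env[off].mean()


def test_speech_envelope_mean_idempotent_for_identical_trials():
    import pandas as pd
    fs = 512.0
    rng = np.random.default_rng(6)
    burst = rng.uniform(0.5, 1.0, int(2 * fs))
    audio = np.zeros(int(10 * fs))
    audio[int(1 * fs):int(3 * fs)] = burst
    audio[int(5 * fs):int(7 * fs)] = burst
    trials = pd.DataFrame({"trial": [0, 1], "stimulus_id": ["s00", "s00"],
                           "delay_ms": [0, 0], "speech_onset_s": [1.0, 5.0],
                           "duration_s": [2.0, 2.0]})
    both = de.speech_envelope(audio, fs, trials, "s00", 0).envelope
    single = de.speech_envelope(audio, fs, trials.iloc[:1], "s00", 0).envelope
    np.testing.assert_allclose(both, single, rtol=1e-9)
    with pytest.raises(WarpingError):
        de.speech_envelope(audio, fs, trials, "s99", 0)


# ------------------------------------------------- warp-normalized contrast -

def test_stretch_only_plant_yields_no_post_warp_divergence():
    clean = 0
    for seed in range(10):
        c = generate_stretch_cohort(seed=seed)
        rep = warped_paired_contrast(c["env0"], c["env200"], c["series"])
        if rep["result"].onset is None:
            clean += 1
    assert clean >= 9


def test_amplitude_plant_survives_warping_with_correct_onset():
    hits = 0
    for seed in range(10):
        c = generate_stretch_cohort(seed=seed, amplitude_gain=1.5, gain_onset_s=0.8)
        rep = warped_paired_contrast(c["env0"], c["env200"], c["series"])
        if rep["result"].onset is not None and abs(rep["result"].onset - 0.8) <= 0.05:
            hits += 1
    assert hits >= 9


def test_post_warp_durations_match_on_stretch_only_plant():
    c = generate_stretch_cohort(seed=0)
    rep = warped_paired_contrast(c["env0"], c["env200"], c["series"])
    diffs = [abs(d1 - d0) for d0, d1 in rep["durations_post"].values()]
    assert np.mean(diffs) <= 0.010  # one 10-ms bin on average
    pre = [d1 - d0 for d0, d1 in rep["durations_pre"].values()]
    assert np.mean(pre) > 0.3  # before warping the stretch is plainly visible
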
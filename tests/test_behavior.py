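"""Articulation durations, delay-effect ANOVA, matching, quartile controls."""

import itertools

import numpy as np
import pandas as pd
import pytest

import daf_ecog as de
from daf_ecog.behavior import (articulation_duration, behavior_anova,
                               control_contrasts, match_by_duration,
                               percentile_split)
from daf_ecog.config import SynthConfig
from daf_ecog.exceptions import SelectionError


# ------------------------------------------------- articulation duration ---

def test_duration_of_planted_support():
    fs = 512.0
    t = np.arange(int(4 * fs)) / fs
    env = ((t >= 0.5) & (t <= 2.5)).astype(float)
    assert articulation_duration(env, fs) == pytest.approx(2.0, abs=0.06)


def test_duration_of_silence_is_missing():
    assert np.isnan(articulation_duration(np.zeros(1000), 512.0))


def test_duration_recovery_under_noise():
    """Planted 3.418-s utterance with additive noise: recovered within 50 ms
    on average over seeded draws."""
    fs = 512.0
    t = np.arange(int(5 * fs)) / fs
    tmpl = de.envelope_template("s01", "sentence", duration=3.418, time_step=0.01)
    env = np.interp(t, 0.4 + 0.01 * np.arange(tmpl.size), tmpl, left=0, right=0)
    errs = []
    for seed in range(100):
        rng = np.random.default_rng([31, seed])
        noisy = env + rng.normal(0, 0.02, env.size)
        errs.append(articulation_duration(noisy, fs) - 3.418)
    assert abs(np.mean(errs)) <= 0.05


def test_full_path_durations_track_planted_table(word_cohort_full):
    rec = word_cohort_full["rec"]
    trials = word_cohort_full["trials"]
    for _, row in trials.head(5).iterrows():
        i0 = int((row.speech_onset_s - 0.3) * rec.fs)
        i1 = int((row.speech_onset_s + row.duration_s + 1.0) * rec.fs)
        d = articulation_duration(rec.aux["microphone"][i0:i1], rec.fs)
        assert d == pytest.approx(row.duration_s, abs=0.08)


# ----------------------------------------------------------------- ANOVA ---

def _dur_frame(rows):
    return pd.DataFrame(rows, columns=["trial", "participant", "delay_ms", "duration_s"])


def test_anova_no_delay_effect_gives_f0_p1():
    rows = []
    k = 0
    for p, base in (("P0", 1.0), ("P1", 2.0)):
        for d in (0, 50, 100, 200):
            for extra in (0.0, 0.2):  # identical pattern in every delay cell
                rows.append((k, p, d, base + extra))
                k += 1
    res = behavior_anova(_dur_frame(rows))
    assert res.f_delay == pytest.approx(0.0, abs=1e-20)
    assert res.p_delay == pytest.approx(1.0)


def test_anova_planted_slope_is_highly_significant():
    cfg = SynthConfig(n_participants=3, task="sentence", n_trials_per_delay=6,
                      n_electrodes_per_roi={"STG": 1}, duration_noise_sd=0.0, seed=2)
    res = behavior_anova(de.generate_trial_table(cfg))
    assert res.p_delay < 1e-6
    assert res.cell_means.shape == (3, 4)


def test_anova_matches_closed_form_two_way_sums_of_squares():
    """Balanced 2x4 fixture with 3 trials per cell, F computed from textbook
    main-effect sums of squares."""
    rng = np.random.default_rng(7)
    rows, k = [], 0
    for p in ("P0", "P1"):
        for d in (0, 50, 100, 200):
            for _ in range(3):
                rows.append((k, p, d, 2.0 + 0.002 * d + (0.3 if p == "P1" else 0)
                             + rng.normal(0, 0.1)))
                k += 1
    df = _dur_frame(rows)
    res = behavior_anova(df)
    y = df.duration_s.to_numpy()
    grand = y.mean()
    ss_delay = sum(6 * (df[df.delay_ms == d].duration_s.mean() - grand) ** 2
                   for d in (0, 50, 100, 200))
    ss_part = sum(12 * (df[df.participant == p].duration_s.mean() - grand) ** 2
                  for p in ("P0", "P1"))
    cell_means = df.groupby(["participant", "delay_ms"]).duration_s.transform("mean")
    fitted = (df.delay_ms.map(df.groupby("delay_ms").duration_s.mean())
              + df.participant.map(df.groupby("participant").duration_s.mean()) - grand)
    ss_res = np.sum((y - fitted) ** 2)
    f_hand = (ss_delay / 3) / (ss_res / (24 - 1 - 3 - 1))
    assert res.f_delay == pytest.approx(f_hand, rel=1e-9)


def test_anova_requires_filled_design():
    rows = [(0, "P0", 0, 1.0), (1, "P0", 50, 1.1), (2, "P1", 0, 1.2)]
    with pytest.raises(SelectionError, match="cells"):
        behavior_anova(_dur_frame(rows))


# -------------------------------------------------------------- matching ---

def _match_trials(d0, d200, stimulus="s00"):
    rows = []
    for i, d in enumerate(d0):
        rows.append({"trial": i, "stimulus_id": stimulus, "delay_ms": 0, "duration_s": d})
    for j, d in enumerate(d200):
        rows.append({"trial": 100 + j, "stimulus_id": stimulus, "delay_ms": 200,
                     "duration_s": d})
    return pd.DataFrame(rows)


def test_match_single_feasible_pair():
    m = match_by_duration(_match_trials([2.00, 2.50], [2.005, 3.00]))
    assert m.pairs == [(0, 100)]
    assert m.n_unmatched == 2


def test_match_strict_tolerance_boundary():
    m = match_by_duration(_match_trials([2.00], [2.010]))
    assert m.pairs == []


def brute_force_max_matching(d0, d200, tol=0.010):
    best = 0
    k = min(len(d0), len(d200))
    for size in range(k, 0, -1):
        for lhs in itertools.combinations(range(len(d0)), size):
            for rhs in itertools.permutations(range(len(d200)), size):
                if all(abs(d0[i] - d200[j]) < tol for i, j in zip(lhs, rhs)):
                    return size
    return 0


def test_match_cardinality_equals_bruteforce_oracle():
    rng = np.random.default_rng(9)
    for _ in range(30):
        d0 = np.round(rng.normal(2.8, 0.02, rng.integers(1, 7)), 3)
        d200 = np.round(rng.normal(2.8, 0.02, rng.integers(1, 7)), 3)
        got = len(match_by_duration(_match_trials(d0, d200)).pairs)
        assert got == brute_force_max_matching(d0, d200)


def test_match_pairs_respect_tolerance_and_uniqueness():
    rng = np.random.default_rng(10)
    tr = _match_trials(rng.normal(2.8, 0.05, 30), rng.normal(2.8, 0.05, 30))
    m = match_by_duration(tr)
    durs = dict(zip(tr.trial, tr.duration_s))
    seen = set()
    for a, b in m.pairs:
        assert abs(durs[a] - durs[b]) < 0.010
        assert a not in seen and b not in seen
        seen.update((a, b))


# ------------------------------------------------------- percentile split ---

def test_percentile_split_integers_1_to_8():
    groups = percentile_split(np.arange(1.0, 9.0))
    assert [g.tolist() for g in groups] == [[0, 1], [2, 3], [4, 5], [6, 7]]


def test_percentile_split_all_ties_single_group_with_warning():
    with pytest.warns(UserWarning, match="degenerate"):
        groups = percentile_split(np.full(8, 2.5), np.arange(8))
    assert len(groups[0]) == 8 and all(len(g) == 0 for g in groups[1:])


def test_percentile_split_partitions_random_input():
    rng = np.random.default_rng(11)
    d = rng.normal(3.0, 0.4, 100)
    ids = np.arange(100)
    groups = percentile_split(d, ids)
    assert sorted(np.concatenate(groups).tolist()) == ids.tolist()
    assert [len(g) for g in groups] == [25, 25, 25, 25]
    # groups ordered by duration
    assert d[groups[0]].max() <= d[groups[3]].min() + 1e-12
    with pytest.raises(SelectionError):
        percentile_split(np.ones(3))


# ------------------------------------------------------ control contrasts ---

def _plant(seed, amplitude_by, **kw):
    defaults = dict(n_participants=1, n_electrodes_per_roi={"STG": 2, "vPreCG": 2},
                    task="sentence", n_trials_per_delay=36, duration_slope=0.0,
                    noise_sd=10.0, seed=seed)
    defaults.update(kw)
    cfg = SynthConfig(**defaults)
    tr = de.generate_trial_table(cfg)
    el = de.generate_electrode_table(cfg)
    if amplitude_by == "delay":
        hg = de.generate_high_gamma(cfg, tr, el)
    else:
        hg = de.generate_high_gamma(cfg, tr, el, amplitude_by="duration",
                                    duration_gain=0.5)
    return hg, tr, el


def test_delay_amplitude_plant_dissociation():
    """Amplitude scales with delay, duration does not: the duration-matched
    contrast fires in auditory ROIs while the percentile split stays null."""
    hg, tr, el = _plant(0, "delay", duration_noise_sd=0.05)
    m = control_contrasts(hg, tr, el, "matched_duration")
    p = control_contrasts(hg, tr, el, "percentile")
    assert m["n_pairs"] >= 2
    assert m["by_roi"]["STG"].onset is not None
    assert np.nanmean(m["by_roi"]["STG"].statistic_series) > 0  # 200 ms > no delay
    assert m["by_roi"]["vPreCG"].onset is None
    assert p["by_roi"]["STG"].onset is None


def test_duration_amplitude_plant_dissociation():
    hg, tr, el = _plant(1, "duration",
                        auditory_gain_per_delay=(1, 1, 1, 1),
                        duration_noise_sd=0.35)
    m = control_contrasts(hg, tr, el, "matched_duration")
    p = control_contrasts(hg, tr, el, "percentile")
    if m["by_roi"]:
        assert m["by_roi"]["STG"].onset is None
    assert p["by_roi"]["STG"].onset is not None


def test_control_contrast_empty_matching_reports_no_pairs():
    hg, tr, el = _plant(2, "delay", duration_noise_sd=0.0)
    tr = tr.copy()
    # push the two conditions far apart so no pair can match
    tr.loc[tr.delay_ms == 200, "duration_s"] += 5.0
    rep = control_contrasts(hg, tr, el, "matched_duration")
    assert rep["n_pairs"] == 0 and "warning" in rep
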
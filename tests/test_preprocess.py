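"""Signal-chain contracts: CAR, notch, epoching, multitaper, percent change,
response duration."""

import numpy as np
import pytest

import daf_ecog as de
from daf_ecog.containers import EpochSet, RawRecording, TimeFrequencyPower
from daf_ecog.exceptions import (NumericalDegeneracyError, ParameterError,
                                 PreprocessingError)
from daf_ecog.preprocess import (TFR_FREQS, band_power, baseline_band_power,
                                 response_duration_fwqm)


def _rec(signals, fs=512.0, aux=None):
    return RawRecording(signals=np.asarray(signals, float), fs=fs,
                        electrode_ids=[f"e{i}" for i in range(len(signals))],
                        aux=aux or {}, participant="P00")


# ---------------------------------------------------------------- CAR ------

def test_car_zero_mean_pair_passes_through():
    x = np.sin(np.linspace(0, 10, 512))
    rec = de.common_average_reference(_rec([x, -x]))
    np.testing.assert_allclose(rec.signals[0], x, atol=1e-12)


def test_car_removes_common_mode():
    x = np.random.default_rng(0).standard_normal(256)
    rec = de.common_average_reference(_rec([x, x, x]))
    np.testing.assert_allclose(rec.signals, 0, atol=1e-12)


def test_car_matches_hand_arithmetic():
    m = np.array([[1.0, 2.0, 3.0, 4.0],
                  [4.0, 0.0, 2.0, 2.0],
                  [1.0, 4.0, 1.0, 0.0]])
    rec = de.common_average_reference(_rec(m))
    np.testing.assert_allclose(rec.signals, m - m.mean(axis=0))


def test_car_idempotent():
    m = np.random.default_rng(1).standard_normal((4, 100))
    once = de.common_average_reference(_rec(m))
    twice = de.common_average_reference(once)
    np.testing.assert_allclose(once.signals, twice.signals, atol=1e-12)


def test_car_requires_two_electrodes():
    with pytest.raises(PreprocessingError):
        de.common_average_reference(_rec(np.ones((2, 10))), exclude={"e0"})


# ---------------------------------------------------------------- notch ----

def test_notch_attenuates_line_and_spares_passband():
    fs = 512.0
    t = np.arange(int(10 * fs)) / fs
    tone60 = np.sin(2 * np.pi * 60 * t)
    tone100 = np.sin(2 * np.pi * 100 * t)
    out60 = de.remove_line_noise(_rec([tone60]), (60.0,)).signals[0]
    out100 = de.remove_line_noise(_rec([tone100]), (60.0,)).signals[0]
    core = slice(int(fs), -int(fs))  # ignore filter edges
    assert np.sqrt(np.mean(out60[core] ** 2)) <= 0.03 * np.sqrt(np.mean(tone60[core] ** 2))
    assert abs(np.sqrt(np.mean(out100[core] ** 2)) / np.sqrt(np.mean(tone100[core] ** 2)) - 1) < 0.01


def test_notch_empty_list_is_identity():
    m = np.random.default_rng(2).standard_normal((2, 256))
    out = de.remove_line_noise(_rec(m), ())
    np.testing.assert_array_equal(out.signals, m)


def test_notch_rejects_frequency_at_nyquist():
    with pytest.raises(ParameterError):
        de.remove_line_noise(_rec(np.ones((1, 100))), (256.0,))


# ---------------------------------------------------------------- epoch ----

def _toy_trials(onsets, fs=512.0):
    import pandas as pd
    return pd.DataFrame({"trial": range(len(onsets)), "participant": "P00",
                         "stimulus_onset_s": np.asarray(onsets) - 0.75,
                         "speech_onset_s": onsets})


def test_epoch_window_durations_match_tasks():
    fs = 512.0
    rec = _rec(np.random.default_rng(3).standard_normal((2, int(30 * fs))))
    word = de.epoch(rec, _toy_trials([5.0, 15.0]), window=(-1.5, 3.5))
    assert word.time_axis[-1] - word.time_axis[0] == pytest.approx(5.0, abs=1 / fs)
    sent = de.epoch(rec, _toy_trials([8.0]), window=(-1.5, 5.5))
    assert sent.time_axis[-1] - sent.time_axis[0] == pytest.approx(7.0, abs=1 / fs)
    assert word.time_axis[np.argmin(np.abs(word.time_axis))] == 0.0


def test_epoch_rejects_out_of_bounds_trial_keeps_rest():
    rec = _rec(np.random.default_rng(4).standard_normal((1, int(20 * 512.0))))
    es = de.epoch(rec, _toy_trials([0.2, 10.0]), window=(-1.5, 3.5))
    assert list(es.trial_index) == [1]
    assert es.rejected == [0]
    with pytest.raises(PreprocessingError):
        de.epoch(rec, _toy_trials([0.2]), window=(-1.5, 3.5))


# ------------------------------------------------------------- multitaper --

def _tone_epochs(freq=100.0, fs=512.0, dur=2.0, n_trials=1):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    data = np.tile(x, (n_trials, 1, 1))
    return EpochSet(data=data, time_axis=t - dur / 2, fs=fs,
                    window=(-dur / 2, dur / 2), trial_index=np.arange(n_trials),
                    electrode_ids=["e0"])


def test_multitaper_tone_peaks_at_its_frequency_bin():
    tfr = de.multitaper_tfr(_tone_epochs(100.0))
    p = np.nanmean(tfr.power[0, 0], axis=1)
    assert tfr.freqs[np.argmax(p)] == 100.0
    far = np.abs(tfr.freqs - 100.0) >= 25.0
    assert 10 * np.log10(p.max() / p[far].max()) >= 20.0


def test_multitaper_zero_signal_gives_zero_power():
    es = _tone_epochs(100.0)
    es.data = np.zeros_like(es.data)
    tfr = de.multitaper_tfr(es)
    assert np.nanmax(tfr.power) == 0.0


def test_multitaper_grid_and_edges():
    tfr = de.multitaper_tfr(_tone_epochs(100.0, dur=2.0))
    assert tfr.power.shape[-1] == int(np.floor(2.0 / 0.010)) + 1
    np.testing.assert_array_equal(tfr.freqs, np.arange(10.0, 201.0, 5.0))
    # edge bins (window half-width 0.1 s) are missing, not zero
    assert np.isnan(tfr.power[0, 0, 0, 0]) and np.isnan(tfr.power[0, 0, 0, -1])
    assert not np.isnan(tfr.power[0, 0, 0, tfr.power.shape[-1] // 2])


def test_multitaper_white_noise_flat_over_band():
    rng = np.random.default_rng(5)
    fs, dur, n = 512.0, 1.0, 50
    data = rng.standard_normal((n, 1, int(dur * fs)))
    es = EpochSet(data=data, time_axis=np.arange(int(dur * fs)) / fs - 0.5, fs=fs,
                  window=(-0.5, 0.5), trial_index=np.arange(n), electrode_ids=["e0"])
    tfr = de.multitaper_tfr(es)
    band = (tfr.freqs >= 70) & (tfr.freqs <= 150)
    mean_p = np.nanmean(tfr.power[:, 0][:, band, :], axis=(0, 2))
    sem = np.nanstd(np.nanmean(tfr.power[:, 0][:, band, :], axis=2), axis=0) / np.sqrt(n)
    grand = mean_p.mean()
    assert np.all(np.abs(mean_p - grand) <= 2.5 * sem + 0.05 * grand)


def test_multitaper_rejects_short_epoch():
    es = _tone_epochs(100.0, dur=0.1)
    with pytest.raises(ParameterError):
        de.multitaper_tfr(es)


# ---------------------------------------------------------- percent change -

def _const_tfr(level, n_trials=2, n_bins=50):
    power = np.full((n_trials, 1, TFR_FREQS.size, n_bins), float(level))
    return TimeFrequencyPower(power=power, freqs=TFR_FREQS,
                              times=0.01 * np.arange(n_bins),
                              trial_index=np.arange(n_trials), electrode_ids=["e0"])


def test_percent_change_constant_power_is_exactly_zero():
    tfr = _const_tfr(7.5)
    hg = de.high_gamma_percent_change(tfr, np.array([7.5]))
    np.testing.assert_array_equal(hg.values, 0.0)


def test_percent_change_arithmetic():
    tfr = _const_tfr(10.0)
    tfr.power[0, 0, :, 3] = 15.0
    hg = de.high_gamma_percent_change(tfr, np.array([10.0]))
    assert hg.values[0, 0, 3] == pytest.approx(50.0)


def test_percent_change_uses_pooled_baseline():
    # two trials with unequal baselines: pooled B = 15 -> +100% at P=30,
    # unlike per-trial normalization (which would give +200% on trial 0)
    tfr = _const_tfr(10.0, n_trials=2)
    tfr.power[1] = 20.0
    tfr.power[0, 0, :, 5] = 30.0
    pooled_b = np.array([15.0])
    hg = de.high_gamma_percent_change(tfr, pooled_b)
    assert hg.values[0, 0, 5] == pytest.approx(100.0)
    assert hg.values[1, 0, 5] == pytest.approx(100.0 * (20 - 15) / 15)


def test_percent_change_gain_invariance():
    rng = np.random.default_rng(6)
    power = rng.uniform(1, 2, size=(3, 1, TFR_FREQS.size, 30))
    tfr = TimeFrequencyPower(power=power, freqs=TFR_FREQS,
                             times=0.01 * np.arange(30),
                             trial_index=np.arange(3), electrode_ids=["e0"])
    b = np.array([1.5])
    hg1 = de.high_gamma_percent_change(tfr, b)
    tfr2 = TimeFrequencyPower(power=4.0 * power, freqs=TFR_FREQS,
                              times=tfr.times, trial_index=tfr.trial_index,
                              electrode_ids=["e0"])
    hg2 = de.high_gamma_percent_change(tfr2, 4.0 * b)
    np.testing.assert_allclose(hg1.values, hg2.values, rtol=1e-12)


def test_percent_change_nonpositive_baseline_names_electrode():
    with pytest.raises(NumericalDegeneracyError, match="e0"):
        de.high_gamma_percent_change(_const_tfr(1.0), np.array([0.0]))


# ----------------------------------------------------------------- FWQM ----

def test_fwqm_triangle():
    t = np.arange(0, 2.001, 0.01)
    y = np.where(t <= 1.0, t, 2.0 - t)
    assert response_duration_fwqm(y, t) == pytest.approx(1.5, abs=1e-9)


def test_fwqm_rectangular_pulse():
    t = np.arange(0, 2.001, 0.01)
    y = ((t >= 0.6) & (t < 1.4)).astype(float)
    assert response_duration_fwqm(y, t) == pytest.approx(0.8, abs=0.011)


def test_fwqm_gaussian_closed_form():
    # FWQM of a Gaussian = 2*sigma*sqrt(2 ln 4)
    sigma = 0.2
    expected = 2 * sigma * np.sqrt(2 * np.log(4.0))
    t = np.arange(-1.5, 1.5, 0.01)
    rng = np.random.default_rng(7)
    durs = []
    for _ in range(100):
        y = np.exp(-0.5 * (t / sigma) ** 2) + rng.normal(0, 0.01, t.size)
        durs.append(response_duration_fwqm(y, t))
    assert abs(np.mean(durs) - expected) <= 0.03


def test_fwqm_scale_invariant_and_degenerate():
    t = np.arange(0, 1.001, 0.01)
    y = np.sin(np.pi * t)
    d1 = response_duration_fwqm(y, t)
    d2 = response_duration_fwqm(123.4 * y, t)
    assert d1 == pytest.approx(d2, rel=1e-12)
    assert np.isnan(response_duration_fwqm(-np.ones(10), np.arange(10) * 0.01))


# --------------------------------------------------------------- baseline --

def test_baseline_band_power_positive_on_cohort(word_cohort_full):
    b = baseline_band_power(word_cohort_full["rec"], word_cohort_full["trials"])
    assert b.shape == (word_cohort_full["rec"].n_electrodes,)
    assert np.all(b > 0)
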
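"""Raw ECoG to speech-locked percent-change high-gamma responses.

The chain follows the standard intracranial workflow: common average
reference, zero-phase notch filters at the 60/120/180 Hz line harmonics,
event-locked epoching, multitaper time-frequency decomposition (3 Slepian
tapers, 10-200 Hz in 5-Hz steps, 200-ms windows every 10 ms, +/-10 Hz
half-bandwidth), band-averaging over 70-150 Hz, and conversion to percent
signal change against a per-electrode baseline pooled over all trials in the
-500..-100 ms window before stimulus onset.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.signal.windows import dpss

from .config import EPOCH_WINDOWS
from .containers import EpochSet, HighGammaResponse, RawRecording, TimeFrequencyPower
from .exceptions import NumericalDegeneracyError, ParameterError, PreprocessingError

__all__ = [
    "common_average_reference", "remove_line_noise", "epoch", "multitaper_tfr",
    "band_power", "high_gamma_percent_change", "response_duration_fwqm",
    "compute_high_gamma",
]

HIGH_GAMMA_BAND = (70.0, 150.0)
TFR_FREQS = np.arange(10.0, 200.0 + 1e-9, 5.0)
TFR_WINDOW = 0.200          # s, temporal smoothing
TFR_HALF_BW = 10.0          # Hz, frequency smoothing (half-bandwidth)
TFR_N_TAPERS = 3
TIME_STEP = 0.010           # s


def common_average_reference(rec: RawRecording, exclude: set | None = None) -> RawRecording:
    """Subtract the across-electrode mean from every (non-excluded) electrode.

    Excluded electrodes are dropped from the output; auxiliary channels pass
    through untouched. Idempotent: applying CAR twice equals applying once.
    """
    exclude = set(exclude or ())
    keep = [i for i, e in enumerate(rec.electrode_ids) if e not in exclude]
    if len(keep) < 2:
        raise PreprocessingError("common average reference needs >= 2 non-excluded electrodes")
    sig = rec.signals[keep]
    sig = sig - sig.mean(axis=0, keepdims=True)
    return RawRecording(signals=sig, fs=rec.fs,
                        electrode_ids=[rec.electrode_ids[i] for i in keep],
                        aux=dict(rec.aux), participant=rec.participant)


def remove_line_noise(rec: RawRecording, freqs=(60.0, 120.0, 180.0),
                      bandwidth: float = 3.0) -> RawRecording:
    """Zero-phase IIR notch filters at each listed frequency.

    Each notch attenuates the target frequency by well over 30 dB (zero-phase
    application squares the magnitude response) while leaving the passband
    +/-5 Hz away essentially untouched (< 1 dB). An empty frequency list is
    the identity transform.
    """
    freqs = tuple(freqs)
    if not freqs:
        return rec
    for f in freqs:
        if f >= rec.fs / 2:
            raise ParameterError(f"notch frequency {f} Hz >= Nyquist ({rec.fs / 2} Hz)")
    sig = rec.signals.copy()
    for f in freqs:
        b, a = sps.iirnotch(f, f / bandwidth, fs=rec.fs)
        sig = sps.filtfilt(b, a, sig, axis=1)
    return RawRecording(signals=sig, fs=rec.fs, electrode_ids=list(rec.electrode_ids),
                        aux=dict(rec.aux), participant=rec.participant)


def epoch(rec: RawRecording, trials: pd.DataFrame, lock: str = "speech_onset",
          window: tuple = (-1.5, 3.5)) -> EpochSet:
    """Cut event-locked epochs; sample at time 0 is the locking event.

    Trials whose window exceeds the recording bounds are rejected (their ids
    are reported on the returned object as ``rejected``).
    """
    col = {"speech_onset": "speech_onset_s", "stimulus_onset": "stimulus_onset_s"}.get(lock)
    if col is None:
        raise ParameterError(f"lock must be speech_onset|stimulus_onset, got {lock!r}")
    tr = trials[trials["participant"] == rec.participant] if "participant" in trials else trials
    n_pre = int(round(-window[0] * rec.fs))
    n_post = int(round(window[1] * rec.fs))
    kept, rejected, data = [], [], []
    for _, row in tr.iterrows():
        c = int(round(row[col] * rec.fs))
        if c - n_pre < 0 or c + n_post >= rec.n_samples:
            rejected.append(int(row["trial"]))
            continue
        data.append(rec.signals[:, c - n_pre: c + n_post + 1])
        kept.append(int(row["trial"]))
    if not kept:
        raise PreprocessingError("no trial fits within the recording bounds")
    es = EpochSet(data=np.stack(data), time_axis=(np.arange(-n_pre, n_post + 1) / rec.fs),
                  fs=rec.fs, window=tuple(window), trial_index=np.asarray(kept),
                  electrode_ids=list(rec.electrode_ids), lock=lock)
    es.rejected = rejected
    return es


def _dpss_bank(m: int, fs: float, freqs: np.ndarray):
    """(m, n_tapers*n_freqs) complex demodulation matrix for windowed DFT."""
    nw = TFR_WINDOW * TFR_HALF_BW  # time-halfbandwidth product = 2.0
    tapers = dpss(m, NW=nw, Kmax=TFR_N_TAPERS)  # (K, m)
    t = np.arange(m) / fs
    phase = np.exp(-2j * np.pi * np.outer(t, freqs))     # (m, F)
    bank = (tapers[:, :, None] * phase[None, :, :])       # (K, m, F)
    return bank.transpose(1, 0, 2).reshape(m, -1)         # (m, K*F)


def multitaper_tfr(epochs: EpochSet, freqs: np.ndarray = TFR_FREQS,
                   time_step: float = TIME_STEP) -> TimeFrequencyPower:
    """Multitaper power on an exact 10-ms output grid.

    For every output bin, a 200-ms window centered on the nearest raw sample
    is projected onto 3 DPSS tapers (time-halfbandwidth product 2, i.e.
    +/-10 Hz smoothing) and the taper power estimates are averaged. Output
    bins whose window would exceed the epoch are NaN (missing), never
    zero-padded.
    """
    m = int(round(TFR_WINDOW * epochs.fs)) | 1  # odd length, centered windows
    if epochs.data.shape[-1] < m:
        raise ParameterError("epoch shorter than the multitaper smoothing window")
    freqs = np.asarray(freqs, dtype=float)
    t0, t1 = epochs.window
    n_bins = int(np.floor((t1 - t0) / time_step + 1e-9)) + 1
    times = t0 + time_step * np.arange(n_bins)
    centers = np.round((times - epochs.time_axis[0]) * epochs.fs).astype(int)
    half = m // 2
    n_samp = epochs.data.shape[-1]
    valid = (centers - half >= 0) & (centers + half < n_samp)
    bank = _dpss_bank(m, epochs.fs, freqs)  # (m, K*F)
    n_trials, n_elec = epochs.data.shape[:2]
    power = np.full((n_trials, n_elec, freqs.size, n_bins), np.nan)
    idx = centers[valid][:, None] + np.arange(-half, half + 1)[None, :]  # (B, m)
    for e in range(n_elec):
        x = epochs.data[:, e, :]                       # (T, S)
        wins = x[:, idx]                               # (T, B, m)
        proj = wins.reshape(-1, m) @ bank              # (T*B, K*F)
        p = (proj.real ** 2 + proj.imag ** 2).reshape(
            n_trials, idx.shape[0], TFR_N_TAPERS, freqs.size).mean(axis=2)
        power[:, e, :, valid] = p.transpose(1, 0, 2)
    return TimeFrequencyPower(power=power, freqs=freqs, times=times,
                              trial_index=epochs.trial_index,
                              electrode_ids=list(epochs.electrode_ids),
                              lock=epochs.lock)


def band_power(tfr: TimeFrequencyPower, band: tuple = HIGH_GAMMA_BAND) -> np.ndarray:
    """Average power over the frequency bins inside ``band`` (inclusive)."""
    sel = (tfr.freqs >= band[0] - 1e-9) & (tfr.freqs <= band[1] + 1e-9)
    if not np.any(sel):
        raise ParameterError(f"no frequency bins inside band {band}")
    return tfr.power[:, :, sel, :].mean(axis=2)


def high_gamma_percent_change(tfr: TimeFrequencyPower,
                              baseline_power: np.ndarray, *,
                              task: str = "word",
                              band: tuple = HIGH_GAMMA_BAND) -> HighGammaResponse:
    """Band-average 70-150 Hz power and normalize to percent change.

    ``baseline_power`` is the per-electrode mean band power pooled across all
    trials over the baseline window (computed on stimulus-locked epochs; see
    :func:`baseline_band_power`). A constant-power signal maps to exactly 0%.
    """
    p = band_power(tfr, band)
    b = np.asarray(baseline_power, dtype=float)
    if b.shape != (p.shape[1],):
        raise ParameterError("baseline_power must have one entry per electrode")
    bad = ~(b > 0)
    if np.any(bad):
        names = [tfr.electrode_ids[i] for i in np.flatnonzero(bad)]
        raise NumericalDegeneracyError(f"non-positive baseline power for electrodes {names}")
    values = 100.0 * (p - b[None, :, None]) / b[None, :, None]
    return HighGammaResponse(values=values, times=tfr.times,
                             trial_index=tfr.trial_index,
                             electrode_ids=list(tfr.electrode_ids),
                             task=task, baseline_power=b)


def baseline_band_power(rec: RawRecording, trials: pd.DataFrame,
                        baseline_window: tuple = (-0.5, -0.1),
                        band: tuple = HIGH_GAMMA_BAND) -> np.ndarray:
    """Per-electrode band power pooled over all trials in the pre-stimulus
    baseline window (stimulus-onset locked)."""
    pad = TFR_WINDOW / 2 + 0.02
    es = epoch(rec, trials, lock="stimulus_onset",
               window=(baseline_window[0] - pad, baseline_window[1] + pad))
    tfr = multitaper_tfr(es)
    p = band_power(tfr, band)
    in_win = (tfr.times >= baseline_window[0] - 1e-9) & (tfr.times <= baseline_window[1] + 1e-9)
    return np.nanmean(p[:, :, in_win], axis=(0, 2))


def response_duration_fwqm(mean_response: np.ndarray, times: np.ndarray):
    """Full width at quarter maximum of a response curve, in seconds.

    Returns the time difference between the outermost crossings of 25% of
    the curve's maximum, located by linear interpolation between bins; NaN
    (with no crossing defined) when the maximum is not positive.
    """
    y = np.asarray(mean_response, dtype=float)
    t = np.asarray(times, dtype=float)
    ok = np.isfinite(y)
    y, t = y[ok], t[ok]
    if y.size == 0 or np.nanmax(y) <= 0:
        return float("nan")
    thr = 0.25 * np.max(y)
    above = y >= thr
    first = int(np.argmax(above))
    last = int(len(y) - 1 - np.argmax(above[::-1]))
    if first == 0:
        t_first = t[0]
    else:
        y0, y1 = y[first - 1], y[first]
        t_first = t[first - 1] + (thr - y0) / (y1 - y0) * (t[first] - t[first - 1])
    if last == len(y) - 1:
        t_last = t[-1]
    else:
        y0, y1 = y[last], y[last + 1]
        t_last = t[last] + (y0 - thr) / (y0 - y1) * (t[last + 1] - t[last])
    return float(t_last - t_first)


def compute_high_gamma(rec: RawRecording, trials: pd.DataFrame, task: str, *,
                       exclude: set | None = None,
                       line_freqs=(60.0, 120.0, 180.0),
                       baseline_window: tuple = (-0.5, -0.1)) -> HighGammaResponse:
    """Full preprocessing chain for one participant's recording.

    CAR -> line-noise notches -> speech-locked epochs (task-dependent window)
    -> multitaper TFR -> 70-150 Hz band average -> percent change against the
    stimulus-locked pooled baseline.
    """
    rec = common_average_reference(rec, exclude=exclude)
    rec = remove_line_noise(rec, line_freqs)
    b = baseline_band_power(rec, trials, baseline_window)
    es = epoch(rec, trials, lock="speech_onset", window=EPOCH_WINDOWS[task])
    tfr = multitaper_tfr(es)
    hg = high_gamma_percent_change(tfr, b, task=task)
    hg.baseline_window = tuple(baseline_window)
    return hg
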
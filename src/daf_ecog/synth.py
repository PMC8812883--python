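"""Synthetic delayed-auditory-feedback (DAF) cohorts.

Generates trial tables, electrode tables, speech-envelope templates, and
either continuous 512-Hz recordings (the full signal path: pink background,
amplitude-modulated 70-150 Hz bursts, 60/120/180 Hz line noise, auxiliary
trigger/microphone/feedback channels) or percent-change high-gamma responses
directly on the 10-ms analysis grid (the fast path used for Monte-Carlo
calibration).

Planted structure mirrors what the downstream analysis assumes:

* two response archetypes — post-onset "auditory" responses whose amplitude
  scales with feedback delay, and pre-onset "motor" responses insensitive to
  delay (word task) by default;
* articulation durations that elongate with delay (more for sentences than
  words) plus trial noise;
* per-stimulus speech-envelope templates that stretch with articulation
  duration.

Randomness is organized as one stream per (participant, purpose) derived
from the master seed, so adding participants never perturbs earlier ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps

from .config import (AUDITORY_ROIS, DEFAULT_AUDITORY, DEFAULT_MOTOR, EPOCH_WINDOWS,
                     N_STIMULI, ResponseArchetype, SynthConfig)
from .containers import HighGammaResponse, RawRecording
from .exceptions import GenerationError

__all__ = [
    "generate_trial_table", "generate_electrode_table", "generate_recording",
    "generate_high_gamma", "generate_cohort", "archetype_envelope",
    "envelope_template", "make_fixture", "generate_stretch_cohort",
    "ROI_GEOMETRY",
]

# purpose codes for per-participant RNG streams
_RNG_TRIALS, _RNG_SIGNAL, _RNG_HG, _RNG_ELEC = 0, 1, 2, 3

#: (MNI center x/y/z, FreeSurfer label) used for synthetic electrode placement.
ROI_GEOMETRY = {
    "STG": ((-62.0, -20.0, 2.0), "superiortemporal"),
    "SMG": ((-58.0, -45.0, 30.0), "supramarginal"),
    "vPreCG": ((-58.0, -5.0, 20.0), "precentral"),
    "dPreCG": ((-45.0, -10.0, 52.0), "precentral"),
    "postCG": ((-50.0, -22.0, 45.0), "postcentral"),
    "IFG": ((-52.0, 18.0, 12.0), "parsopercularis"),
}


def _rng(cfg_seed: int, participant_index: int, purpose: int) -> np.random.Generator:
    return np.random.default_rng([int(cfg_seed), int(participant_index), int(purpose)])


def _participant_ids(cfg: SynthConfig) -> list:
    return [f"P{p:02d}" for p in range(cfg.n_participants)]


# ---------------------------------------------------------------------------
# trial and electrode tables
# ---------------------------------------------------------------------------

def generate_trial_table(cfg: SynthConfig) -> pd.DataFrame:
    """One row per trial, delay conditions balanced at ``n_trials_per_delay``.

    Articulation duration is ``duration_base + duration_slope * delay_index``
    plus Gaussian trial noise, truncated positive; trial order is randomized
    under the per-participant stream. Trials are laid out sequentially in
    time with at least the configured inter-trial interval.
    """
    t_max = cfg.epoch_window[1]
    rows = []
    trial_no = 0
    for p_idx, pid in enumerate(_participant_ids(cfg)):
        rng = _rng(cfg.seed, p_idx, _RNG_TRIALS)
        delays, stims = [], []
        for d_idx in range(cfg.n_delays):
            delays += [d_idx] * cfg.n_trials_per_delay
            stims += [i % cfg.n_stimuli for i in range(cfg.n_trials_per_delay)]
        order = rng.permutation(len(delays))
        speech_onset = 3.0
        for k in order:
            d_idx, s_idx = delays[k], stims[k]
            dur = (cfg.duration_base + cfg.duration_slope * d_idx
                   + rng.normal(0.0, cfg.duration_noise_sd))
            dur = max(dur, 0.1 * cfg.duration_base)
            rows.append({
                "trial": trial_no,
                "participant": pid,
                "task": cfg.task,
                "stimulus_id": f"{cfg.task[0]}{s_idx:02d}",
                "delay_ms": cfg.delays[d_idx],
                "delay_index": d_idx,
                "stimulus_onset_s": speech_onset - cfg.speech_latency,
                "speech_onset_s": speech_onset,
                "duration_s": dur,
            })
            trial_no += 1
            # next stimulus appears after the utterance + ITI, and never
            # inside the current trial's epoch tail
            next_stim = speech_onset + max(dur + cfg.iti, t_max + 0.3)
            speech_onset = next_stim + cfg.speech_latency
    return pd.DataFrame(rows)


def generate_electrode_table(cfg: SynthConfig) -> pd.DataFrame:
    """Electrodes per ROI with plausible MNI coordinates and archetypes.

    STG/SMG electrodes carry the auditory archetype; precentral, postcentral
    and IFG electrodes carry the motor archetype. Dorsal precentral
    electrodes keep |z| >= 40 and ventral ones |z| < 40 so that anatomical
    regrouping from coordinates reproduces the intended ROI.
    """
    rows = []
    for p_idx, pid in enumerate(_participant_ids(cfg)):
        rng = _rng(cfg.seed, p_idx, _RNG_ELEC)
        for roi, count in cfg.n_electrodes_per_roi.items():
            (cx, cy, cz), label = ROI_GEOMETRY[roi]
            for k in range(count):
                jitter = rng.uniform(-3.0, 3.0, size=3)
                z = cz + jitter[2]
                if roi == "dPreCG":
                    z = max(z, 41.0)
                elif roi == "vPreCG":
                    z = min(z, 38.0)
                rows.append({
                    "electrode_id": f"{pid}_{roi}{k}",
                    "participant": pid,
                    "mni_x": cx + jitter[0],
                    "mni_y": cy + jitter[1],
                    "mni_z": z,
                    "fs_label": label,
                    "roi": roi,
                    "archetype": "auditory" if roi in AUDITORY_ROIS else "motor",
                })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# response envelopes and speech-envelope templates
# ---------------------------------------------------------------------------

def archetype_envelope(times: np.ndarray, arche: ResponseArchetype,
                       duration: float) -> np.ndarray:
    """Percent-change response envelope, time-locked to speech onset.

    Raised-cosine rise from ``onset`` to ``peak_time``, plateau at
    ``peak_amplitude`` until articulation ends, raised-cosine decay over
    ``decay`` seconds. Longer articulation stretches only the sustained
    (post-peak) portion; onset and peak latencies stay fixed.
    """
    times = np.asarray(times, dtype=float)
    env = np.zeros_like(times)
    sustain_end = max(duration, arche.peak_time)
    rise = (times >= arche.onset) & (times < arche.peak_time)
    if np.any(rise):
        u = (times[rise] - arche.onset) / (arche.peak_time - arche.onset)
        env[rise] = 0.5 - 0.5 * np.cos(np.pi * u)
    env[(times >= arche.peak_time) & (times < sustain_end)] = 1.0
    fall = (times >= sustain_end) & (times < sustain_end + arche.decay)
    if np.any(fall):
        u = (times[fall] - sustain_end) / arche.decay
        env[fall] = 0.5 + 0.5 * np.cos(np.pi * u)
    return arche.peak_amplitude * env


def envelope_template(stimulus_id: str, task: str, duration: float | None = None,
                      time_step: float = 0.010) -> np.ndarray:
    """Nonnegative speech-envelope template sampled at 10-ms steps.

    One template per stimulus (10 word templates, 6 sentence templates):
    a sum of syllable-rate bumps with seeded amplitudes, peak-normalized,
    stretched to ``duration`` (defaults to the task's base articulation
    duration). The same stimulus id always yields the same template shape.
    """
    idx = int(stimulus_id[1:]) if stimulus_id[1:].isdigit() else abs(hash(stimulus_id)) % 97
    if idx >= N_STIMULI.get(task, 10):
        raise GenerationError(f"stimulus {stimulus_id!r} outside the {task} inventory")
    if duration is None:
        duration = SynthConfig._DURATION_DEFAULTS[task][0]
    n_syll = 3 if task == "word" else 24
    rng = np.random.default_rng([9, 0 if task == "word" else 1, idx])
    amps = rng.uniform(0.6, 1.0, size=n_syll)
    u = np.linspace(0.0, 1.0, 200)
    centers = (np.arange(n_syll) + 0.5) / n_syll
    width = 0.35 / n_syll
    tmpl = np.zeros_like(u)
    for a, c in zip(amps, centers):
        tmpl += a * np.exp(-0.5 * ((u - c) / width) ** 2)
    tmpl /= tmpl.max()
    n = max(int(round(duration / time_step)), 2)
    return np.interp(np.linspace(0, 1, n), u, tmpl)


# ---------------------------------------------------------------------------
# fast path: percent-change responses on the 10-ms grid
# ---------------------------------------------------------------------------

def response_time_axis(task: str, time_step: float = 0.010) -> np.ndarray:
    t0, t1 = EPOCH_WINDOWS[task]
    n = int(np.floor((t1 - t0) / time_step + 1e-9)) + 1
    return t0 + time_step * np.arange(n)


def generate_high_gamma(cfg: SynthConfig, trials: pd.DataFrame | None = None,
                        electrodes: pd.DataFrame | None = None, *,
                        gain_onset_s: float | None = None,
                        amplitude_by: str = "delay",
                        duration_gain: float = 0.0) -> HighGammaResponse:
    """Percent-change responses generated directly on the analysis grid.

    Each trial x electrode response is the electrode archetype's envelope
    (stretched to the trial's articulation duration), multiplied by a
    delay-dependent gain, plus white Gaussian bin noise of SD ``noise_sd``.

    Parameters
    ----------
    gain_onset_s : float, optional
        When given, the delay gain applies only from this time onward
        (plants a divergence at a known post-onset latency).
    amplitude_by : {"delay", "duration"}
        "delay": gain indexed by delay condition (the default plant).
        "duration": gain = 1 + duration_gain * (duration - duration_base),
        i.e., amplitude depends on articulation duration only.
    """
    if amplitude_by not in ("delay", "duration"):
        raise GenerationError(f"amplitude_by must be delay|duration, got {amplitude_by!r}")
    if trials is None:
        trials = generate_trial_table(cfg)
    if electrodes is None:
        electrodes = generate_electrode_table(cfg)
    times = response_time_axis(cfg.task)
    n_bins = times.size
    values = np.zeros((len(trials), len(electrodes), n_bins))
    arche_of = {"auditory": DEFAULT_AUDITORY, "motor": DEFAULT_MOTOR}
    pids = list(_participant_ids(cfg))
    elec_arr = electrodes.reset_index(drop=True)
    trials = trials.reset_index(drop=True)
    for p_idx, pid in enumerate(pids):
        rng = _rng(cfg.seed, p_idx, _RNG_HG)
        t_rows = np.flatnonzero(trials["participant"].values == pid)
        e_rows = np.flatnonzero(elec_arr["participant"].values == pid)
        if t_rows.size == 0 or e_rows.size == 0:
            continue
        for ti in t_rows:
            dur = trials.at[ti, "duration_s"]
            d_idx = int(trials.at[ti, "delay_index"])
            base = {k: archetype_envelope(times, a, dur) for k, a in arche_of.items()}
            for ei in e_rows:
                kind = elec_arr.at[ei, "archetype"]
                if amplitude_by == "delay":
                    g = cfg.gains_for(kind)[d_idx]
                else:
                    g = 1.0 + duration_gain * (dur - cfg.duration_base)
                env = base[kind]
                if gain_onset_s is None:
                    values[ti, ei] = g * env
                else:
                    values[ti, ei] = env * np.where(times >= gain_onset_s - 1e-9, g, 1.0)
            if cfg.noise_sd > 0:
                values[ti, e_rows] += rng.normal(0.0, cfg.noise_sd,
                                                 size=(e_rows.size, n_bins))
    return HighGammaResponse(values=values, times=times,
                             trial_index=trials["trial"].values,
                             electrode_ids=list(elec_arr["electrode_id"]),
                             task=cfg.task)


# ---------------------------------------------------------------------------
# full path: continuous 512-Hz recordings
# ---------------------------------------------------------------------------

def _pink_noise(rng: np.random.Generator, n: int, fs: float) -> np.ndarray:
    """1/f-shaped background noise, unit overall RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, 1.0 / fs)
    spec *= 1.0 / np.sqrt(np.maximum(f, 1.0))
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_rms(x: np.ndarray, fs: float, lo: float = 70.0, hi: float = 150.0) -> float:
    spec = np.fft.rfft(x)
    f = np.fft.rfftfreq(x.size, 1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    return np.fft.irfft(spec, n=x.size).std()


def generate_recording(cfg: SynthConfig, trials: pd.DataFrame,
                       electrodes: pd.DataFrame, participant: str) -> RawRecording:
    """Continuous recording for one participant.

    Per electrode: pink background + per-trial high-gamma bursts
    (70-150 Hz band-limited noise carriers amplitude-modulated by the
    archetype envelope, scaled so that the in-band power increase matches the
    intended percent change) + 60/120/180 Hz line noise. Auxiliary channels:
    ``trigger`` (amplitude 1.0 impulse at stimulus onset, 0.5 at speech
    onset), ``microphone`` (stimulus envelope template stretched to the
    trial's articulation duration), ``feedback`` (microphone shifted by the
    trial's feedback delay, rounded to whole samples).
    """
    fs = cfg.sampling_rate
    p_ids = _participant_ids(cfg)
    if participant not in p_ids:
        raise GenerationError(f"unknown participant {participant!r}")
    p_idx = p_ids.index(participant)
    tr = trials[trials["participant"] == participant].sort_values("stimulus_onset_s")
    if len(tr) == 0:
        raise GenerationError(f"no trials for participant {participant!r}")
    # inter-trial gap check: next stimulus must follow the previous utterance by >= 1 s
    ends = (tr["speech_onset_s"] + tr["duration_s"]).values[:-1]
    starts = tr["stimulus_onset_s"].values[1:]
    if np.any(starts - ends < 1.0 - 1e-9):
        raise GenerationError("overlapping trials: inter-trial gap < 1 s")
    el = electrodes[electrodes["participant"] == participant].reset_index(drop=True)
    t_end = tr["speech_onset_s"].values[-1] + cfg.epoch_window[1] + 1.0
    n = int(np.ceil(t_end * fs))
    rng = _rng(cfg.seed, p_idx, _RNG_SIGNAL)

    arche_of = {"auditory": DEFAULT_AUDITORY, "motor": DEFAULT_MOTOR}
    sos = sps.butter(4, [70.0, 150.0], btype="bandpass", fs=fs, output="sos")
    signals = np.empty((len(el), n))
    line_t = np.arange(n) / fs
    for ei in range(len(el)):
        bg = _pink_noise(rng, n, fs)
        sigma_b = _band_rms(bg, fs)
        x = bg
        kind = el.at[ei, "archetype"]
        arche = arche_of[kind]
        gains = cfg.gains_for(kind)
        for _, row in tr.iterrows():
            onset_t = row["speech_onset_s"] + arche.onset - 0.1
            stop_t = row["speech_onset_s"] + max(row["duration_s"], arche.peak_time) + arche.decay + 0.1
            i0, i1 = max(int(onset_t * fs), 0), min(int(stop_t * fs) + 1, n)
            seg_t = np.arange(i0, i1) / fs - row["speech_onset_s"]
            env_pct = gains[int(row["delay_index"])] * archetype_envelope(
                seg_t, arche, row["duration_s"])
            if cfg.noise_sd > 0:
                # trial-to-trial amplitude jitter in percent-change units
                env_pct = np.maximum(env_pct + rng.normal(0.0, cfg.noise_sd) *
                                     (env_pct > 0), 0.0)
            carrier = sps.sosfiltfilt(sos, rng.standard_normal(seg_t.size + 256))[128:-128]
            carrier /= carrier.std()
            x[i0:i1] = x[i0:i1] + sigma_b * np.sqrt(env_pct / 100.0) * carrier
        for f_line in (60.0, 120.0, 180.0):
            x += 0.5 * np.sin(2 * np.pi * f_line * line_t + rng.uniform(0, 2 * np.pi))
        signals[ei] = x

    mic = np.zeros(n)
    trig = np.zeros(n)
    feedback = np.zeros(n)
    for _, row in tr.iterrows():
        trig[int(row["stimulus_onset_s"] * fs)] = 1.0
        trig[int(row["speech_onset_s"] * fs)] = max(trig[int(row["speech_onset_s"] * fs)], 0.5)
        dur = row["duration_s"]
        m = int(round(dur * fs))
        tmpl = envelope_template(row["stimulus_id"], cfg.task)
        seg = np.interp(np.linspace(0, 1, m), np.linspace(0, 1, tmpl.size), tmpl)
        i0 = int(row["speech_onset_s"] * fs)
        i1 = min(i0 + m, n)
        mic[i0:i1] = seg[:i1 - i0]
        shift = int(round(row["delay_ms"] / 1000.0 * fs))
        j0, j1 = i0 + shift, min(i1 + shift, n)
        feedback[j0:j1] = seg[:j1 - j0]
    return RawRecording(signals=signals, fs=fs,
                        electrode_ids=list(el["electrode_id"]),
                        aux={"trigger": trig, "microphone": mic, "feedback": feedback},
                        participant=participant)


def generate_cohort(cfg: SynthConfig):
    """Trial table, electrode table, and one recording per participant."""
    trials = generate_trial_table(cfg)
    electrodes = generate_electrode_table(cfg)
    recs = {pid: generate_recording(cfg, trials, electrodes, pid)
            for pid in _participant_ids(cfg)}
    return trials, electrodes, recs


# ---------------------------------------------------------------------------
# warp plants: responses that are exact time-stretches across conditions
# ---------------------------------------------------------------------------

def generate_stretch_cohort(n_stimuli: int = 6, n_trials_per_cell: int = 3,
                            stretch: float = 1.25, amplitude_gain: float = 1.0,
                            gain_onset_s: float | None = None,
                            noise_sd: float = 5.0, base_duration: float = 2.761,
                            time_step: float = 0.010, seed: int = 0) -> dict:
    """Paired no-delay / 200-ms cohort where the 200-ms condition is a pure
    time-stretch of the no-delay condition, optionally with an amplitude gain
    applied from source time ``gain_onset_s`` onward.

    Returns a dict with per-stimulus speech envelopes on each condition's
    10-ms grid and per-trial neural series, for exercising DTW path transfer.
    """
    rng = np.random.default_rng([int(seed), 77])
    env0, env200, series = {}, {}, {}
    durations = {}
    for k in range(n_stimuli):
        sid = f"s{k:02d}"
        dur0 = base_duration * rng.uniform(0.92, 1.08)
        dur200 = dur0 * stretch
        durations[sid] = (dur0, dur200)
        env0[sid] = envelope_template(sid, "sentence", duration=dur0, time_step=time_step)
        env200[sid] = envelope_template(sid, "sentence", duration=dur200, time_step=time_step)
        n0, n200 = env0[sid].size, env200[sid].size
        t0 = time_step * np.arange(n0)
        base_curve = archetype_envelope(t0, DEFAULT_AUDITORY, dur0 - 0.3)
        # 200-ms condition: same curve read at source time t/stretch
        t200_src = time_step * np.arange(n200) / stretch
        curve200 = np.interp(t200_src, t0, base_curve)
        if amplitude_gain != 1.0 and gain_onset_s is not None:
            curve200 = curve200 * np.where(t200_src >= gain_onset_s - 1e-9,
                                           amplitude_gain, 1.0)
        elif amplitude_gain != 1.0:
            curve200 = amplitude_gain * curve200
        series[(sid, 0)] = base_curve + rng.normal(0, noise_sd, (n_trials_per_cell, n0))
        series[(sid, 200)] = curve200 + rng.normal(0, noise_sd, (n_trials_per_cell, n200))
    return {"stimuli": [f"s{k:02d}" for k in range(n_stimuli)],
            "env0": env0, "env200": env200, "series": series,
            "durations": durations, "time_step": time_step,
            "gain_onset_s": gain_onset_s, "stretch": stretch}


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def _fixture_two_archetype_minimal() -> dict:
    cfg = SynthConfig(n_participants=1,
                      n_electrodes_per_roi={"STG": 1, "vPreCG": 1},
                      task="word", n_trials_per_delay=4, delays=(0, 200),
                      auditory_gain_per_delay=(1.0, 1.8),
                      motor_gain_per_delay=(1.0, 1.0),
                      duration_noise_sd=0.0, noise_sd=0.0, seed=11)
    trials = generate_trial_table(cfg)
    electrodes = generate_electrode_table(cfg)
    hg = generate_high_gamma(cfg, trials, electrodes)
    return {"cfg": cfg, "trials": trials, "electrodes": electrodes, "hg": hg,
            "expected": {"n_trials": 8,
                         "auditory_peak_ratio": 1.8,
                         "archetypes": dict(zip(electrodes["electrode_id"],
                                                electrodes["archetype"]))}}


def _fixture_flat_null() -> dict:
    cfg = SynthConfig(n_participants=1,
                      n_electrodes_per_roi={"STG": 2, "vPreCG": 1},
                      task="sentence", n_trials_per_delay=10,
                      auditory_gain_per_delay=(1.0, 1.0, 1.0, 1.0),
                      motor_gain_per_delay=(1.0, 1.0, 1.0, 1.0),
                      duration_slope=0.0, duration_noise_sd=0.05,
                      noise_sd=10.0, seed=13)
    trials = generate_trial_table(cfg)
    electrodes = generate_electrode_table(cfg)
    hg = generate_high_gamma(cfg, trials, electrodes)
    return {"cfg": cfg, "trials": trials, "electrodes": electrodes, "hg": hg,
            "expected": {"divergence_onset": None}}


def _fixture_planted_divergence() -> dict:
    cfg = SynthConfig(n_participants=1,
                      n_electrodes_per_roi={"STG": 3},
                      task="sentence", n_trials_per_delay=40,
                      auditory_gain_per_delay=(1.0, 1.2, 1.4, 1.8),
                      duration_slope=0.0, duration_noise_sd=0.05,
                      noise_sd=10.0, seed=17)
    trials = generate_trial_table(cfg)
    electrodes = generate_electrode_table(cfg)
    hg = generate_high_gamma(cfg, trials, electrodes, gain_onset_s=1.0)
    return {"cfg": cfg, "trials": trials, "electrodes": electrodes, "hg": hg,
            "expected": {"divergence_onset": 1.0}}


_FIXTURES = {
    "two-archetype-minimal": _fixture_two_archetype_minimal,
    "flat-null": _fixture_flat_null,
    "planted-divergence": _fixture_planted_divergence,
}


def make_fixture(name: str) -> dict:
    """Small deterministic input bundle for unit tests.

    Raises LookupError listing the registered fixtures for unknown names.
    """
    try:
        builder = _FIXTURES[name]
    except KeyError:
        raise LookupError(
            f"unknown fixture {name!r}; registered: {sorted(_FIXTURES)}") from None
    return builder()
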
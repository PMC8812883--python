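"""Articulation-duration normalization by DTW path transfer.

To compare conditions whose utterances differ in length, the no-delay and
200-ms-delay speech envelopes of each stimulus are aligned with dynamic time
warping (absolute-difference local cost; steps (1,0), (0,1), (1,1);
boundary-constrained), and the resulting path — not the neural data — is
used to map each 200-ms-condition neural trial onto the no-delay time grid.
Trial-averaged warped responses are then compared per stimulus with the
paired-t divergence pipeline, and full-width-quarter-maximum durations are
checked before/after warping to confirm temporal alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy import signal as sps

from .config import DivergenceConfig
from .containers import HighGammaResponse, WarpPath
from .divergence import DivergenceDetector
from .exceptions import WarpingError
from .preprocess import response_duration_fwqm

__all__ = ["EnvelopeByStimulus", "speech_envelope", "dtw_align", "apply_warp",
           "warped_paired_contrast", "warp_normalized_contrast"]


@dataclass
class EnvelopeByStimulus:
    """Trial-averaged speech envelope of one (stimulus, condition) cell on
    the 10-ms grid starting at speech onset."""

    stimulus_id: str
    condition: int
    envelope: np.ndarray
    time_step: float = 0.010
    n_trials: int = 0


@njit(cache=False)
def _dtw_table(a, b):  # pragma: no cover - exercised via dtw_align
    n, m = a.size, b.size
    D = np.empty((n, m))
    D[0, 0] = abs(a[0] - b[0])
    for j in range(1, m):
        D[0, j] = D[0, j - 1] + abs(a[0] - b[j])
    for i in range(1, n):
        D[i, 0] = D[i - 1, 0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = D[i - 1, j - 1]
            if D[i - 1, j] < best:
                best = D[i - 1, j]
            if D[i, j - 1] < best:
                best = D[i, j - 1]
            D[i, j] = abs(a[i] - b[j]) + best
    return D


def dtw_align(source: np.ndarray, target: np.ndarray) -> WarpPath:
    """Optimal monotone boundary-constrained alignment of two envelopes.

    Local cost is the absolute amplitude difference; the step set is
    {(1,0), (0,1), (1,1)}. On equal accumulated cost the diagonal step is
    preferred over (1,0) over (0,1), making paths deterministic.
    """
    a = np.asarray(source, dtype=float).ravel()
    b = np.asarray(target, dtype=float).ravel()
    if a.size == 0 or b.size == 0:
        raise WarpingError("cannot align empty envelopes")
    D = _dtw_table(a, b)
    i, j = a.size - 1, b.size - 1
    pairs = [(i, j)]
    while i > 0 or j > 0:
        if i > 0 and j > 0:
            best = min(D[i - 1, j - 1], D[i - 1, j], D[i, j - 1])
            if D[i - 1, j - 1] == best:
                i, j = i - 1, j - 1
            elif D[i - 1, j] == best:
                i -= 1
            else:
                j -= 1
        elif i > 0:
            i -= 1
        else:
            j -= 1
        pairs.append((i, j))
    pairs.reverse()
    return WarpPath(pairs=np.asarray(pairs), cost=float(D[-1, -1]),
                    n_source=a.size, n_target=b.size)


def apply_warp(path: WarpPath, series: np.ndarray) -> np.ndarray:
    """Map a target-grid series onto the source grid along a warping path.

    Output bin i is the mean of the series values at all target bins j with
    (i, j) on the path (many-to-one collapses by arithmetic mean). Works on
    1-D series or stacked (trials, bins) arrays; output length is the
    path's source length.
    """
    series = np.asarray(series, dtype=float)
    if series.shape[-1] != path.n_target:
        raise WarpingError(
            f"series length {series.shape[-1]} does not match path target axis {path.n_target}")
    out_shape = series.shape[:-1] + (path.n_source,)
    out = np.empty(out_shape)
    for i, js in enumerate(path.target_bins_for_source()):
        out[..., i] = series[..., js].mean(axis=-1)
    return out


def speech_envelope(audio: np.ndarray, fs: float, trials: pd.DataFrame,
                    stimulus_id: str, condition: int, *,
                    time_step: float = 0.010, span: float | None = None) -> EnvelopeByStimulus:
    """Trial-averaged speech envelope of one (stimulus, delay) cell.

    Per trial, the magnitude spectrogram of the microphone epoch (from
    speech onset over the cell's articulation span) is averaged across
    frequencies and interpolated onto the 10-ms grid; the per-trial
    envelopes are then averaged.
    """
    cell = trials[(trials["stimulus_id"] == stimulus_id)
                  & (trials["delay_ms"] == condition)]
    if len(cell) == 0:
        raise WarpingError(f"no trials for stimulus {stimulus_id!r} at {condition} ms")
    if span is None:
        span = float(cell["duration_s"].max())
    n_bins = max(int(round(span / time_step)), 2)
    grid = time_step * np.arange(n_bins)
    nperseg = max(int(round(0.05 * fs)), 8)
    hop = max(int(round(time_step * fs / 2)), 1)
    envs = []
    for _, row in cell.iterrows():
        i0 = int(round(row["speech_onset_s"] * fs))
        i1 = min(i0 + int(np.ceil(span * fs)) + nperseg, audio.size)
        seg = audio[i0:i1]
        f, t, S = sps.spectrogram(seg, fs=fs, nperseg=nperseg,
                                  noverlap=nperseg - hop, mode="magnitude")
        env = S.mean(axis=0)
        envs.append(np.interp(grid, t, env, left=env[0], right=env[-1]))
    return EnvelopeByStimulus(stimulus_id=stimulus_id, condition=condition,
                              envelope=np.mean(envs, axis=0),
                              time_step=time_step, n_trials=len(envs))


def warped_paired_contrast(env_source: dict, env_target: dict, series: dict,
                           *, conditions=(0, 200),
                           cfg: DivergenceConfig | None = None,
                           time_step: float = 0.010) -> dict:
    """Core warp-then-compare contrast on per-stimulus arrays.

    Parameters
    ----------
    env_source, env_target : dict stimulus -> envelope (10-ms grid)
        Speech envelopes of the no-delay (source) and 200-ms (target)
        conditions.
    series : dict (stimulus, condition) -> (n_trials, n_bins) arrays
        Neural responses on the matching condition grids.

    Per stimulus the target-condition trials are warped onto the source
    grid along the envelope DTW path and trial-averaged; the paired-t
    divergence pipeline then runs across stimuli at each source bin
    (bins beyond a stimulus's support are excluded). FWQM durations of the
    trial-mean curves are reported before and after warping, with a paired t
    test of the post-warp durations.
    """
    cfg = cfg or DivergenceConfig(test="paired_t")
    c0, c1 = conditions
    stimuli = sorted(env_source)
    if set(stimuli) != set(env_target):
        missing = sorted(set(env_source) ^ set(env_target))
        stimuli = sorted(set(env_source) & set(env_target))
        if not stimuli:
            raise WarpingError(f"no stimulus has both conditions (missing: {missing})")
    n_max = max(env_source[s].size for s in stimuli)
    X = np.full((len(stimuli), 2, n_max), np.nan)
    dur_pre, dur_post = {}, {}
    paths = {}
    for k, s in enumerate(stimuli):
        path = dtw_align(env_source[s], env_target[s])
        paths[s] = path
        src_mean = np.asarray(series[(s, c0)]).mean(axis=0)
        tgt_trials = np.asarray(series[(s, c1)])
        warped = apply_warp(path, tgt_trials)
        warped_mean = warped.mean(axis=0)
        n0 = src_mean.size
        X[k, 0, :n0] = src_mean
        X[k, 1, :n0] = warped_mean
        t_src = time_step * np.arange(n0)
        t_tgt = time_step * np.arange(path.n_target)
        dur_pre[s] = (response_duration_fwqm(src_mean, t_src),
                      response_duration_fwqm(tgt_trials.mean(axis=0), t_tgt))
        dur_post[s] = (dur_pre[s][0], response_duration_fwqm(warped_mean, t_src))
    det = DivergenceDetector(test="paired_t", alpha_point=cfg.alpha_point,
                             q_fdr=cfg.q_fdr, min_run=cfg.min_run,
                             time_step=cfg.time_step)
    det.fit(X, times=time_step * np.arange(n_max))
    d0 = np.array([dur_post[s][0] for s in stimuli])
    d1 = np.array([dur_post[s][1] for s in stimuli])
    ok = np.isfinite(d0) & np.isfinite(d1)
    if ok.sum() >= 2 and np.std(d1[ok] - d0[ok]) > 0:
        from scipy import stats
        t_stat, p_val = stats.ttest_rel(d1[ok], d0[ok])
        duration_test = {"t": float(t_stat), "p": float(p_val), "n": int(ok.sum())}
    else:
        duration_test = {"t": 0.0, "p": 1.0, "n": int(ok.sum())}
    return {"result": det.result(), "paths": paths, "stimuli": stimuli,
            "durations_pre": dur_pre, "durations_post": dur_post,
            "duration_ttest": duration_test}


def warp_normalized_contrast(hg: HighGammaResponse, trials: pd.DataFrame,
                             audio_by_participant: dict, electrodes: pd.DataFrame,
                             fs: float, cfg: DivergenceConfig | None = None,
                             conditions=(0, 200)) -> dict:
    """Full-path warp contrast per ROI from microphone audio.

    Envelopes come from each participant's microphone channel; neural series
    are ROI-averaged per trial on the post-onset grid trimmed to each cell's
    articulation span. Stimuli missing either condition are dropped.
    Returns a dict roi -> contrast report (see :func:`warped_paired_contrast`).
    """
    cfg = cfg or DivergenceConfig(test="paired_t")
    c0, c1 = conditions
    tr = trials.set_index("trial").loc[hg.trial_index].reset_index()
    step = hg.time_step
    post = hg.times >= -1e-9
    roi_map = dict(zip(electrodes["electrode_id"], electrodes["roi"]))
    rois = sorted({roi_map.get(e) for e in hg.electrode_ids} - {None})
    stimuli = sorted(tr["stimulus_id"].unique())
    env0, env1, spans = {}, {}, {}
    for s in stimuli:
        cells = {c: tr[(tr["stimulus_id"] == s) & (tr["delay_ms"] == c)] for c in (c0, c1)}
        if any(len(c) == 0 for c in cells.values()):
            continue
        for c, store in ((c0, env0), (c1, env1)):
            span = float(cells[c]["duration_s"].max())
            parts = []
            n_tr = 0
            for pid, audio in audio_by_participant.items():
                sub = cells[c][cells[c]["participant"] == pid]
                if len(sub) == 0:
                    continue
                e = speech_envelope(audio, fs, sub, s, c, time_step=step, span=span)
                parts.append(e.envelope * e.n_trials)
                n_tr += e.n_trials
            store[s] = np.sum(parts, axis=0) / n_tr
            spans[(s, c)] = store[s].size
    out = {}
    for roi in rois:
        idx = [i for i, e in enumerate(hg.electrode_ids) if roi_map.get(e) == roi]
        if not idx:
            continue
        roi_resp = hg.values[:, idx, :].mean(axis=1)[:, post]  # (trials, post bins)
        series = {}
        for s in env0:
            for c in (c0, c1):
                rows = np.flatnonzero((tr["stimulus_id"] == s).values
                                      & (tr["delay_ms"] == c).values)
                series[(s, c)] = roi_resp[rows][:, :spans[(s, c)]]
        if not env0:
            raise WarpingError("no stimulus has both contrast conditions")
        out[roi] = warped_paired_contrast(env0, env1, series,
                                          conditions=conditions, cfg=cfg,
                                          time_step=step)
    return out
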
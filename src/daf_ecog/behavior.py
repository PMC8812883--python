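"""Articulation-duration measurement and the two dissociation controls.

DAF slows speech: articulation duration grows with feedback delay. The
delay effect is tested with a fixed-effects ANOVA (delay + participant, to
account for repeated measures). Two controls dissociate feedback delay from
articulation duration: (a) no-delay and 200-ms trials of the same stimulus
matched in duration to within 10 ms, compared with the paired-t divergence
pipeline; (b) 200-ms trials split into duration quartiles, compared with the
ANOVA divergence pipeline.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .config import DivergenceConfig
from .containers import BehaviorResult, HighGammaResponse, MatchedPairs
from .divergence import DivergenceDetector
from .exceptions import SelectionError

__all__ = ["articulation_duration", "behavior_anova", "match_by_duration",
           "percentile_split", "control_contrasts"]


def articulation_duration(audio_epoch: np.ndarray, fs: float, *,
                          threshold_frac: float = 0.2, percentile: float = 95.0,
                          smooth_s: float = 0.05, min_sustain_s: float = 0.05) -> float:
    """Utterance duration from an audio epoch by adaptive energy threshold.

    The squared signal is smoothed with a ``smooth_s`` moving average; the
    threshold is ``threshold_frac`` of the ``percentile``-th percentile of
    the smoothed energy. Onset/offset are the first/last crossings sustained
    for at least ``min_sustain_s``. Returns NaN when nothing is
    suprathreshold (silence).
    """
    x = np.asarray(audio_epoch, dtype=float)
    if x.size == 0:
        return float("nan")
    energy = x ** 2
    w = max(int(round(smooth_s * fs)), 1)
    kernel = np.ones(w) / w
    smoothed = np.convolve(energy, kernel, mode="same")
    ref = np.percentile(smoothed, percentile)
    if ref <= 0:
        return float("nan")
    above = smoothed >= threshold_frac * ref
    min_run = max(int(round(min_sustain_s * fs)), 1)
    onset = offset = None
    i, n = 0, above.size
    while i < n:
        if above[i]:
            j = i
            while j < n and above[j]:
                j += 1
            if j - i >= min_run:
                if onset is None:
                    onset = i
                offset = j
            i = j
        else:
            i += 1
    if onset is None:
        return float("nan")
    return (offset - onset) / fs


def behavior_anova(durations: pd.DataFrame) -> BehaviorResult:
    """Delay effect on articulation duration with participant as a factor.

    Fixed-effects two-factor ANOVA (delay + participant, no interaction) on
    per-trial durations; reports the delay-effect F, degrees of freedom, and
    p, plus the participant x delay cell-mean table.
    """
    df = durations.dropna(subset=["duration_s"]).copy()
    if df["participant"].nunique() < 2 or df["delay_ms"].nunique() < 2:
        raise SelectionError("behavior ANOVA needs >= 2 participants and >= 2 delays")
    counts = df.groupby(["participant", "delay_ms"]).size().unstack(fill_value=0)
    if (counts.values == 0).any():
        empty = [(p, d) for p in counts.index for d in counts.columns
                 if counts.loc[p, d] == 0]
        raise SelectionError(f"empty participant x delay cells: {empty}")
    model = smf.ols("duration_s ~ C(delay_ms) + C(participant)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    row = table.loc["C(delay_ms)"]
    cell_means = df.groupby(["participant", "delay_ms"])["duration_s"].mean().unstack()
    return BehaviorResult(durations=df, cell_means=cell_means,
                          f_delay=float(row["F"]),
                          df_delay=(int(row["df"]), int(table.loc["Residual", "df"])),
                          p_delay=float(row["PR(>F)"]))


def match_by_duration(trials: pd.DataFrame, tolerance: float = 0.010,
                      conditions=(0, 200)) -> MatchedPairs:
    """Duration-matched (no-delay, 200-ms) pairs within each stimulus.

    Maximum-cardinality matching under the strict |difference| < tolerance
    rule, computed per stimulus by a sorted two-pointer sweep (optimal for
    interval-tolerance compatibility on a line); each trial joins at most one
    pair.
    """
    c0, c1 = conditions
    pairs = []
    used = 0
    for _, grp in trials.groupby("stimulus_id"):
        a = grp[grp["delay_ms"] == c0].sort_values("duration_s")
        b = grp[grp["delay_ms"] == c1].sort_values("duration_s")
        da, db = a["duration_s"].to_numpy(), b["duration_s"].to_numpy()
        ia, ib = a["trial"].to_numpy(), b["trial"].to_numpy()
        i = j = 0
        while i < len(da) and j < len(db):
            if abs(da[i] - db[j]) < tolerance - 1e-12:
                pairs.append((int(ia[i]), int(ib[j])))
                i += 1
                j += 1
            elif da[i] < db[j]:
                i += 1
            else:
                j += 1
        used += len(da) + len(db)
    return MatchedPairs(pairs=pairs, n_unmatched=used - 2 * len(pairs),
                        tolerance=tolerance)


def percentile_split(durations: np.ndarray, trial_ids: np.ndarray | None = None):
    """Quartile split of trials by articulation duration.

    Boundaries are the linear-interpolation 25/50/75 empirical percentiles;
    groups are half-open [q_k, q_{k+1}) with ties kept in the lower group.
    Returns a list of 4 arrays of trial ids (or indices) partitioning the
    input.
    """
    d = np.asarray(durations, dtype=float)
    if d.size < 4:
        raise SelectionError("percentile split needs >= 4 trials")
    if trial_ids is None:
        trial_ids = np.arange(d.size)
    trial_ids = np.asarray(trial_ids)
    bounds = np.percentile(d, [25, 50, 75])
    group = np.searchsorted(bounds, d, side="left")
    if np.unique(group).size == 1 and np.unique(d).size == 1:
        warnings.warn("degenerate split: all durations equal; one group holds all trials")
    return [trial_ids[group == g] for g in range(4)]


def control_contrasts(hg: HighGammaResponse, trials: pd.DataFrame,
                      electrodes: pd.DataFrame, which: str,
                      cfg: DivergenceConfig | None = None) -> dict:
    """Per-ROI divergence reports for the two dissociation controls.

    which="matched_duration": duration-matched no-delay vs 200-ms pairs,
    paired t per time bin (alpha 0.01). which="percentile": 200-ms trials in
    duration quartiles, one-way ANOVA per bin (alpha 0.001). Returns
    {"by_roi": {roi: DivergenceResult}, ...bookkeeping...}; an empty
    grouping yields an empty report rather than an error.
    """
    tr = trials.set_index("trial").loc[hg.trial_index].reset_index()
    pos = {int(t): k for k, t in enumerate(hg.trial_index)}
    roi_map = dict(zip(electrodes["electrode_id"], electrodes["roi"]))
    rois = sorted({roi_map.get(e) for e in hg.electrode_ids} - {None})

    def roi_mean(roi):
        idx = [i for i, e in enumerate(hg.electrode_ids) if roi_map.get(e) == roi]
        return hg.values[:, idx, :].mean(axis=1) if idx else None

    out = {"which": which, "by_roi": {}}
    if which == "matched_duration":
        matched = match_by_duration(tr)
        out["n_pairs"] = len(matched.pairs)
        out["pairs"] = matched.pairs
        if len(matched.pairs) < 2:
            out["warning"] = "fewer than 2 duration-matched pairs"
            return out
        cfg = cfg or DivergenceConfig(test="paired_t")
        for roi in rois:
            rm = roi_mean(roi)
            if rm is None:
                continue
            X = np.stack([[rm[pos[t0]], rm[pos[t1]]] for t0, t1 in matched.pairs])
            det = DivergenceDetector(test="paired_t", alpha_point=cfg.alpha_point,
                                     q_fdr=cfg.q_fdr, min_run=cfg.min_run,
                                     time_step=cfg.time_step)
            out["by_roi"][roi] = det.fit(X, times=hg.times).result()
    elif which == "percentile":
        t200 = tr[tr["delay_ms"] == tr["delay_ms"].max()]
        groups = percentile_split(t200["duration_s"].to_numpy(),
                                  t200["trial"].to_numpy())
        out["groups"] = [g.tolist() for g in groups]
        labels = np.concatenate([[g] * len(ids) for g, ids in enumerate(groups)])
        order = np.concatenate(groups)
        if any(len(g) < 2 for g in groups):
            out["warning"] = "a percentile group has fewer than 2 trials"
            return out
        cfg = cfg or DivergenceConfig(test="anova_1way")
        rows = [pos[int(t)] for t in order]
        # compare only while every group still contains speech: bins after the
        # shortest included articulation would confound amplitude with the
        # response simply having ended on short trials
        t_stop = float(t200["duration_s"].min())
        out["t_stop"] = t_stop
        keep = (hg.times >= -1e-9) & (hg.times <= t_stop + 1e-9)
        for roi in rois:
            rm = roi_mean(roi)
            if rm is None:
                continue
            det = DivergenceDetector(test="anova_1way", alpha_point=cfg.alpha_point,
                                     q_fdr=cfg.q_fdr, min_run=cfg.min_run,
                                     time_step=cfg.time_step)
            out["by_roi"][roi] = det.fit(rm[rows][:, keep], labels,
                                         times=hg.times[keep]).result()
    else:
        raise ValueError(f"which must be matched_duration|percentile, got {which!r}")
    return out
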
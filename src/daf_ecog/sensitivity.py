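"""Per-electrode DAF sensitivity: delay-vs-response rank correlation.

The sensitivity index of an electrode is the trial-wise Spearman correlation
between the feedback-delay condition (ordinal) and the mean percent-change
response over a task-dependent window (0-1 s for words, 0-3 s for
sentences). A large positive value marks response enhancement with
increasing delay. A linear-regression slope variant is also provided, and
word/sentence indices are compared electrode-wise with a paired t test.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SENSITIVITY_WINDOWS
from .containers import HighGammaResponse
from .exceptions import SensitivityError

__all__ = ["spearman_rho", "daf_sensitivity", "sensitivity_slope",
           "compare_task_sensitivity"]


def spearman_rho(x: np.ndarray, y: np.ndarray) -> float:
    """Spearman correlation as the Pearson correlation of average ranks.

    Ties get average ranks. A constant input yields rho = 0 (degenerate,
    rather than undefined) so flat electrodes report zero sensitivity.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    rx = stats.rankdata(x, method="average")
    ry = stats.rankdata(y, method="average")
    sx, sy = rx.std(), ry.std()
    if sx == 0 or sy == 0:
        return 0.0
    return float(np.mean((rx - rx.mean()) * (ry - ry.mean())) / (sx * sy))


def _window_means(hg: HighGammaResponse, trials: pd.DataFrame, task: str):
    window = SENSITIVITY_WINDOWS[task]
    mask = hg.window_mask(window)
    if not np.any(mask):
        raise SensitivityError(f"time axis does not cover window {window}")
    tr = trials.set_index("trial").loc[hg.trial_index]
    x = tr["delay_index"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise SensitivityError("need >= 2 distinct delay conditions")
    if x.size < 4:
        raise SensitivityError("need >= 4 trials")
    y = np.nanmean(hg.values[:, :, mask], axis=2)  # (trials, electrodes)
    return x, y, window


def daf_sensitivity(hg: HighGammaResponse, trials: pd.DataFrame,
                    task: str | None = None) -> pd.DataFrame:
    """Sensitivity index per electrode.

    Returns a DataFrame with ``electrode``, ``task``, ``rho``, ``slope``,
    ``n_trials``, ``degenerate`` (True when the response was constant across
    trials and rho was pinned to 0).
    """
    task = task or hg.task
    x, y, window = _window_means(hg, trials, task)
    rows = []
    for e, eid in enumerate(hg.electrode_ids):
        ye = y[:, e]
        rho = spearman_rho(x, ye)
        slope = _ols_slope(x, ye)
        rows.append({"electrode": eid, "task": task, "rho": rho, "slope": slope,
                     "n_trials": int(x.size), "degenerate": bool(np.std(ye) == 0)})
    return pd.DataFrame(rows)


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    denom = np.sum(xc ** 2)
    if denom == 0:
        return 0.0
    return float(np.sum(xc * (y - y.mean())) / denom)


def sensitivity_slope(hg: HighGammaResponse, trials: pd.DataFrame,
                      task: str | None = None) -> pd.DataFrame:
    """OLS slope of window-mean response on delay-condition index."""
    return daf_sensitivity(hg, trials, task)[["electrode", "task", "slope", "n_trials"]]


def compare_task_sensitivity(word: pd.DataFrame, sentence: pd.DataFrame,
                             electrodes: pd.DataFrame | None = None) -> dict:
    """Paired t test of sentence vs word sensitivity over common electrodes.

    Returns the overall test and, when an electrode table with ``roi`` is
    given, one test per ROI. A zero-variance difference yields t = +/-inf
    with p reported as 0.0.
    """
    merged = word.merge(sentence, on="electrode", suffixes=("_word", "_sentence"))
    if len(merged) < 3:
        return {"overall": None, "warning": "fewer than 3 paired electrodes"}

    def paired(df):
        d = df["rho_sentence"].to_numpy() - df["rho_word"].to_numpy()
        n = d.size
        sd = d.std(ddof=1)
        if sd <= 1e-12 * max(np.max(np.abs(d)), 1e-30):  # zero-variance edge
            t = float(np.inf) * np.sign(d.mean()) if d.mean() != 0 else 0.0
            p = 0.0 if d.mean() != 0 else 1.0
        else:
            t, p = stats.ttest_rel(df["rho_sentence"], df["rho_word"])
            t, p = float(t), float(p)
        return {"t": t, "p": p, "dof": n - 1, "n": n,
                "mean_diff": float(d.mean()),
                "direction": "sentence>word" if d.mean() > 0 else "word>=sentence"}

    out = {"overall": paired(merged)}
    if electrodes is not None and "roi" in electrodes:
        roi_map = dict(zip(electrodes["electrode_id"], electrodes["roi"]))
        merged["roi"] = merged["electrode"].map(roi_map)
        by_roi = {}
        for roi, grp in merged.groupby("roi"):
            by_roi[roi] = paired(grp) if len(grp) >= 3 else None
        out["by_roi"] = by_roi
    return out
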
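"""When do responses diverge across delay conditions?

Pointwise tests (one-way ANOVA over the 4 delay conditions, or a paired t
test for two-condition contrasts) at every 10-ms bin, Benjamini-Hochberg FDR
correction across bins (q = 0.05), and a run-length criterion: a divergence
counts only when the pointwise p beats the per-point threshold (0.001 for
the 4-condition ANOVA, 0.01 for pairwise tests) inside the FDR-passing set
for at least 200 consecutive milliseconds. The divergence onset of a region
is the start of its earliest qualifying run.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import DivergenceConfig
from .containers import DivergenceResult, HighGammaResponse
from .exceptions import StatTestError

__all__ = ["pointwise_stats", "fdr_bh", "significant_runs", "DivergenceDetector",
           "divergence_by_region"]


def _anova_series(X: np.ndarray, labels: np.ndarray):
    """Vectorized one-way ANOVA across rows of X at every column.

    Equivalent to scipy.stats.f_oneway per column; columns containing NaN
    yield NaN statistics.
    """
    labels = np.asarray(labels)
    groups = np.unique(labels)
    if groups.size < 2:
        raise StatTestError("one-way ANOVA needs >= 2 conditions")
    n, _ = X.shape
    grand = X.mean(axis=0)
    ss_between = np.zeros(X.shape[1])
    ss_within = np.zeros(X.shape[1])
    df_b = groups.size - 1
    df_w = n - groups.size
    for g in groups:
        rows = X[labels == g]
        if rows.shape[0] < 2:
            raise StatTestError(f"condition {g!r} has fewer than 2 trials")
        gm = rows.mean(axis=0)
        ss_between += rows.shape[0] * (gm - grand) ** 2
        ss_within += ((rows - gm) ** 2).sum(axis=0)
    if df_w <= 0:
        raise StatTestError("not enough trials for the within-group degrees of freedom")
    with np.errstate(divide="ignore", invalid="ignore"):
        F = (ss_between / df_b) / (ss_within / df_w)
    p = stats.f.sf(F, df_b, df_w)
    return F, p


def _paired_t_series(diff: np.ndarray):
    """Vectorized two-sided paired t over rows of a difference matrix."""
    n = diff.shape[0]
    if n < 2:
        raise StatTestError("paired t test needs >= 2 pairs")
    mean = diff.mean(axis=0)
    sd = diff.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = mean / (sd / np.sqrt(n))
    t = np.where((sd == 0) & (mean == 0), 0.0, t)
    p = 2.0 * stats.t.sf(np.abs(t), n - 1)
    p = np.where(np.isinf(t), 0.0, p)
    return t, p


def pointwise_stats(X: np.ndarray, condition: np.ndarray | None,
                    cfg: DivergenceConfig):
    """Per-bin test statistic and p-value series.

    For ``anova_1way``, X is (trials, bins) with per-trial condition labels.
    For ``paired_t``, X is (pairs, 2, bins) — the two paired condition
    series — and ``condition`` is ignored. Bins with missing data yield NaN
    and are skipped downstream.
    """
    X = np.asarray(X, dtype=float)
    if cfg.test == "anova_1way":
        if X.ndim != 2:
            raise StatTestError("anova_1way expects X of shape (trials, bins)")
        if condition is None:
            raise StatTestError("anova_1way needs per-trial condition labels")
        valid = ~np.isnan(X).any(axis=0)
        stat = np.full(X.shape[1], np.nan)
        p = np.full(X.shape[1], np.nan)
        if valid.any():
            s, pv = _anova_series(X[:, valid], condition)
            stat[valid], p[valid] = s, pv
        return stat, p
    if X.ndim != 3 or X.shape[1] != 2:
        raise StatTestError("paired_t expects X of shape (pairs, 2, bins)")
    diff = X[:, 1, :] - X[:, 0, :]
    valid = ~np.isnan(diff).any(axis=0)
    stat = np.full(diff.shape[1], np.nan)
    p = np.full(diff.shape[1], np.nan)
    if valid.any():
        s, pv = _paired_t_series(diff[:, valid])
        stat[valid], p[valid] = s, pv
    return stat, p


def fdr_bh(p_series: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q.

    NaN entries are excluded from the family and reported False.
    """
    p = np.asarray(p_series, dtype=float)
    mask = np.zeros(p.shape, dtype=bool)
    valid = ~np.isnan(p)
    if valid.any():
        rej, *_ = multipletests(p[valid], alpha=q, method="fdr_bh")
        mask[valid] = rej
    return mask


def significant_runs(fdr_mask: np.ndarray, p_series: np.ndarray,
                     cfg: DivergenceConfig, times: np.ndarray):
    """Maximal consecutive significant stretches spanning >= min_run.

    A bin is significant iff it passes FDR *and* its pointwise p beats
    ``alpha_point``. Runs are returned as half-open (start_s, end_s)
    intervals (a 20-bin run on the 10-ms grid spans exactly 0.200 s); the
    onset is the earliest run start, or None.
    """
    p = np.asarray(p_series, dtype=float)
    sig = np.asarray(fdr_mask, dtype=bool) & np.less(p, cfg.alpha_point,
                                                     where=~np.isnan(p),
                                                     out=np.zeros(p.shape, bool))
    times = np.asarray(times, dtype=float)
    runs = []
    i = 0
    n = sig.size
    while i < n:
        if not sig[i]:
            i += 1
            continue
        j = i
        while j < n and sig[j]:
            j += 1
        if (j - i) >= cfg.min_run_bins:
            runs.append((float(times[i]), float(times[i] + (j - i) * cfg.time_step)))
        i = j
    onset = runs[0][0] if runs else None
    return runs, onset


class DivergenceDetector:
    """Pointwise test + FDR + run-length divergence detector.

    Estimator-style: ``fit`` computes the statistic/p series, the FDR mask,
    qualifying runs, and the divergence onset as fitted attributes
    (``statistic_series_``, ``p_series_``, ``fdr_mask_``, ``runs_``,
    ``onset_``) and returns self; :meth:`result` packages them as a
    :class:`DivergenceResult`.
    """

    def __init__(self, test: str = "anova_1way", alpha_point: float | None = None,
                 q_fdr: float = 0.05, min_run: float = 0.200,
                 time_step: float = 0.010):
        self.test = test
        self.alpha_point = alpha_point
        self.q_fdr = q_fdr
        self.min_run = min_run
        self.time_step = time_step

    def get_params(self, deep: bool = True) -> dict:
        return {"test": self.test, "alpha_point": self.alpha_point,
                "q_fdr": self.q_fdr, "min_run": self.min_run,
                "time_step": self.time_step}

    def set_params(self, **params) -> "DivergenceDetector":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _config(self) -> DivergenceConfig:
        return DivergenceConfig(test=self.test, alpha_point=self.alpha_point,
                                q_fdr=self.q_fdr, min_run=self.min_run,
                                time_step=self.time_step)

    def fit(self, X, y=None, times=None) -> "DivergenceDetector":
        cfg = self._config()
        X = np.asarray(X, dtype=float)
        n_bins = X.shape[-1]
        if times is None:
            times = cfg.time_step * np.arange(n_bins)
        stat, p = pointwise_stats(X, y, cfg)
        mask = fdr_bh(p, cfg.q_fdr)
        runs, onset = significant_runs(mask, p, cfg, times)
        self.statistic_series_ = stat
        self.p_series_ = p
        self.fdr_mask_ = mask
        self.runs_ = runs
        self.onset_ = onset
        self.times_ = np.asarray(times, dtype=float)
        self.n_units_ = X.shape[0]
        return self

    def result(self) -> DivergenceResult:
        return DivergenceResult(statistic_series=self.statistic_series_,
                                p_series=self.p_series_, fdr_mask=self.fdr_mask_,
                                runs=self.runs_, onset=self.onset_,
                                times=self.times_, test=self.test,
                                n_units=self.n_units_)


def divergence_by_region(hg: HighGammaResponse, trials: pd.DataFrame,
                         electrodes: pd.DataFrame,
                         cfg: DivergenceConfig | None = None,
                         rois=None) -> dict:
    """One-way-ANOVA divergence per ROI, trials pooled across electrodes.

    Within each ROI, every (trial, electrode) response is one observation;
    condition labels are the trial's delay condition. ROIs without
    electrodes in ``hg`` are skipped.
    """
    cfg = cfg or DivergenceConfig()
    if cfg.test != "anova_1way":
        raise StatTestError("divergence_by_region uses the anova_1way test")
    tr = trials.set_index("trial").loc[hg.trial_index]
    labels = tr["delay_index"].to_numpy()
    if np.unique(labels).size < 2:
        raise StatTestError("single delay condition; divergence undefined")
    roi_map = dict(zip(electrodes["electrode_id"], electrodes["roi"]))
    rois = rois or sorted({roi_map.get(e) for e in hg.electrode_ids} - {None})
    out = {}
    for roi in rois:
        idx = [i for i, e in enumerate(hg.electrode_ids) if roi_map.get(e) == roi]
        if not idx:
            continue
        X = np.concatenate([hg.values[:, i, :] for i in idx], axis=0)
        y = np.tile(labels, len(idx))
        det = DivergenceDetector(test="anova_1way", alpha_point=cfg.alpha_point,
                                 q_fdr=cfg.q_fdr, min_run=cfg.min_run,
                                 time_step=cfg.time_step)
        out[roi] = det.fit(X, y, times=hg.times).result()
    return out
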
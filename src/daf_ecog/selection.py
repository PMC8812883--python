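"""Speech-responsive electrode selection and anatomical ROI grouping.

An electrode is selected when its trial-mean percent-change response in the
pre-onset (-0.5..0 s) or the task-dependent post-onset window shows a
significant increase over the -1..-0.6 s baseline (one-sided unpaired t
test, p < 1e-4) *and* the same window has a signal-to-noise ratio
(mean/SD across trials) above 0.7. Electrodes common to both tasks carry
forward. ROIs follow FreeSurfer labels, with precentral electrodes split
dorsal/ventral at |MNI z| = 40.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .config import SelectionCriteria
from .containers import HighGammaResponse
from .exceptions import SelectionError

__all__ = ["ElectrodeSelector", "select_electrodes", "intersect_task_selections",
           "assign_roi", "assign_rois", "ROI_LABELS"]

#: FreeSurfer cortical labels with a direct ROI mapping (precentral is
#: resolved with the MNI z coordinate).
ROI_LABELS = {
    "superiortemporal": "STG",
    "middlesuperiortemporal": "STG",
    "caudalsuperiortemporal": "STG",
    "caudalmiddlefrontal": "dPreCG",
    "parsopercularis": "IFG",
    "parstriangularis": "IFG",
    "postcentral": "postCG",
    "supramarginal": "SMG",
}


def assign_roi(fs_label: str, mni_z: float) -> str:
    """Map one FreeSurfer label (+ MNI z) to the six-ROI scheme.

    Precentral electrodes with |z| >= 40 are dorsal precentral (together with
    caudal middle frontal); |z| < 40 ventral precentral. Unrecognized labels
    map to "other".
    """
    label = str(fs_label).strip().lower().replace("_", "").replace("-", "")
    if label == "precentral":
        return "dPreCG" if abs(mni_z) >= 40.0 else "vPreCG"
    return ROI_LABELS.get(label, "other")


def assign_rois(electrodes: pd.DataFrame) -> pd.DataFrame:
    """Add/overwrite the ``roi`` column from ``fs_label`` and ``mni_z``."""
    out = electrodes.copy()
    out["roi"] = [assign_roi(l, z) for l, z in zip(out["fs_label"], out["mni_z"])]
    return out


class ElectrodeSelector:
    """Dual t-test / SNR speech-responsiveness gate (estimator-style).

    Parameters
    ----------
    criteria : SelectionCriteria
        Thresholds and analysis windows.

    Attributes (after :meth:`fit`)
    ------------------------------
    report_ : DataFrame with electrode, p_pre, p_post, snr_pre, snr_post,
        selected.
    selected_ : list of selected electrode ids.
    """

    def __init__(self, criteria: SelectionCriteria | None = None):
        self.criteria = criteria or SelectionCriteria()

    def get_params(self, deep: bool = True) -> dict:
        return {"criteria": self.criteria}

    def set_params(self, **params) -> "ElectrodeSelector":
        for k, v in params.items():
            setattr(self, k, v)
        return self

    def _window_means(self, hg: HighGammaResponse, window: tuple) -> np.ndarray:
        mask = hg.window_mask(window)
        if not np.any(mask):
            raise SelectionError(f"time axis does not cover window {window}")
        return np.nanmean(hg.values[:, :, mask], axis=2)  # (trials, electrodes)

    def fit(self, hg: HighGammaResponse, task: str | None = None) -> "ElectrodeSelector":
        task = task or hg.task
        crit = self.criteria
        if hg.n_trials < 2:
            raise SelectionError("electrode selection needs >= 2 trials")
        base = self._window_means(hg, crit.baseline_window)
        alternative = "two-sided" if crit.two_sided else "greater"
        rows = []
        for w_name, window in (("pre", crit.pre_window), ("post", crit.post_window(task))):
            means = self._window_means(hg, window)
            t, p = stats.ttest_ind(means, base, axis=0, alternative=alternative)
            mu = means.mean(axis=0)
            sd = means.std(axis=0, ddof=1)
            snr = np.divide(mu, sd, out=np.full_like(mu, np.inf), where=sd > 0)
            rows.append((w_name, p, snr))
        report = pd.DataFrame({"electrode": list(hg.electrode_ids)})
        sel = np.zeros(hg.n_electrodes, dtype=bool)
        for w_name, p, snr in rows:
            report[f"p_{w_name}"] = p
            report[f"snr_{w_name}"] = snr
            sel |= (p < crit.p_threshold) & (snr > crit.snr_threshold)
        report["selected"] = sel
        self.report_ = report
        self.selected_ = list(report.loc[sel, "electrode"])
        return self


def select_electrodes(hg: HighGammaResponse, criteria: SelectionCriteria | None = None,
                      task: str | None = None) -> pd.DataFrame:
    """Functional wrapper over :class:`ElectrodeSelector`; returns the report."""
    return ElectrodeSelector(criteria).fit(hg, task=task).report_


def intersect_task_selections(sel_word, sel_sentence) -> dict:
    """Electrodes selected in both tasks.

    Accepts selection reports (DataFrames with ``electrode``/``selected``) or
    plain iterables of electrode ids; returns the common set with per-task
    counts.
    """
    def ids(sel):
        if isinstance(sel, pd.DataFrame):
            return set(sel.loc[sel["selected"], "electrode"])
        return set(sel)

    w, s = ids(sel_word), ids(sel_sentence)
    common = w & s
    return {"common": sorted(common), "n_word": len(w), "n_sentence": len(s),
            "n_common": len(common)}
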
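"""End-to-end orchestration: synthesis -> preprocessing -> selection ->
clustering -> sensitivity -> divergence -> warp contrast -> controls ->
behavior, with a manifest recording configuration hashes and outputs.

Stages compose the module primitives; cross-participant analyses pool
trials over each participant's electrodes within a region of interest.
"""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as dio
from .behavior import articulation_duration, behavior_anova, match_by_duration, percentile_split
from .clustering import ResponseProfileNMF, build_matrix, label_clusters
from .config import DivergenceConfig, SelectionCriteria, SynthConfig
from .containers import HighGammaResponse
from .divergence import DivergenceDetector
from .exceptions import DafEcogError
from .preprocess import compute_high_gamma
from .selection import ElectrodeSelector, assign_rois, intersect_task_selections
from .sensitivity import compare_task_sensitivity, daf_sensitivity
from .synth import generate_cohort
from .warping import warp_normalized_contrast

__all__ = ["run_all", "roi_trial_means", "pooled_region_divergence",
           "qualitative_reproduction"]

#: Demo cohort: 2 participants x 10 electrodes over the six ROIs; auditory
#: gains rise with delay in both tasks, motor gains only during sentences.
DEMO_COHORT = {
    "synth": {
        "n_participants": 2,
        "n_electrodes_per_roi": {"STG": 3, "SMG": 1, "vPreCG": 2, "dPreCG": 1,
                                 "postCG": 1, "IFG": 1},
        "n_trials_per_delay": 10,
        "noise_sd": 0.0,
    },
    "word": {"motor_gain_per_delay": (1.0, 1.0, 1.0, 1.0)},
    "sentence": {"motor_gain_per_delay": (1.0, 1.1, 1.25, 1.5),
                 "duration_noise_sd": 0.35},
}


def qualitative_reproduction(seed: int = 10, config: dict | None = None) -> dict:
    """End-to-end qualitative pattern on the demo cohort.

    Runs synthesis -> preprocessing -> selection -> word-task NMF clustering
    -> per-task sensitivity, and summarizes the cluster x task pattern:
    cluster assignment accuracy against the planted archetypes, the mean
    sensitivity index of each semantic cluster per task, per-cluster delay
    ANOVAs on window-mean responses, and the electrode-paired sentence vs
    word sensitivity test.
    """
    from scipy import stats as _stats

    config = config or DEMO_COHORT
    base = {**config["synth"], "seed": seed}
    cohorts = {}
    for task in ("word", "sentence"):
        cfg = SynthConfig(**{**base, **config.get(task, {}), "task": task})
        trials, electrodes, recs = generate_cohort(cfg)
        hg = {pid: compute_high_gamma(rec, trials, task) for pid, rec in recs.items()}
        cohorts[task] = {"cfg": cfg, "trials": trials, "electrodes": electrodes,
                         "hg": hg}
    electrodes = cohorts["word"]["electrodes"]

    selections = {}
    for task in ("word", "sentence"):
        selections[task] = pd.concat(
            [ElectrodeSelector().fit(h, task=task).report_
             for h in cohorts[task]["hg"].values()], ignore_index=True)
    common = intersect_task_selections(selections["word"], selections["sentence"])

    matrix = build_matrix(list(cohorts["word"]["hg"].values()), common["common"])
    model = ResponseProfileNMF(n_components=2, n_restarts=10, random_state=seed).fit(matrix)
    sem = label_clusters(model.H_, matrix.times, matrix.n_trials)
    pred = {e: sem["labels"][c] for e, c in zip(matrix.row_index, model.labels_)}
    truth = dict(zip(electrodes["electrode_id"], electrodes["archetype"]))
    accuracy = float(np.mean([(truth[e] == "auditory") == (pred[e] == "auditory-like")
                              for e in matrix.row_index]))

    sens = {}
    for task in ("word", "sentence"):
        sens[task] = pd.concat([daf_sensitivity(h, cohorts[task]["trials"], task)
                                for h in cohorts[task]["hg"].values()],
                               ignore_index=True)
        sens[task]["cluster"] = sens[task]["electrode"].map(pred)
    mean_rho = {task: sens[task].dropna(subset=["cluster"])
                .groupby("cluster")["rho"].mean().to_dict()
                for task in ("word", "sentence")}

    anova = {}
    for task in ("word", "sentence"):
        tr = cohorts[task]["trials"]
        win = {"word": (0.0, 1.0), "sentence": (0.0, 3.0)}[task]
        for lbl in ("auditory-like", "motor-like"):
            obs, lab = [], []
            for h in cohorts[task]["hg"].values():
                m = h.window_mask(win)
                delays = tr.set_index("trial").loc[h.trial_index, "delay_index"].to_numpy()
                for i, e in enumerate(h.electrode_ids):
                    if pred.get(e) == lbl:
                        obs.append(np.nanmean(h.values[:, i, :][:, m], axis=1))
                        lab.append(delays)
            X, y = np.concatenate(obs), np.concatenate(lab)
            F, p = _stats.f_oneway(*[X[y == g] for g in np.unique(y)])
            anova[(task, lbl)] = {"F": float(F), "p": float(p)}

    paired = compare_task_sensitivity(sens["word"], sens["sentence"])
    return {"selection": common, "accuracy": accuracy,
            "cluster_sizes": {lbl: int(sum(v == lbl for v in pred.values()))
                              for lbl in ("auditory-like", "motor-like")},
            "mean_rho": mean_rho, "anova": anova, "paired": paired["overall"],
            "cohorts": cohorts, "pred": pred}


def roi_trial_means(hg_by_participant: dict, trials: pd.DataFrame,
                    electrodes: pd.DataFrame, roi: str):
    """Across participants: per-trial response averaged over the ROI's
    electrodes of the trial's own participant.

    Returns (trial_ids, matrix of shape (n_trials, n_bins)) or None when no
    participant has electrodes in the ROI.
    """
    roi_map = dict(zip(electrodes["electrode_id"], electrodes["roi"]))
    blocks, ids = [], []
    for pid, hg in hg_by_participant.items():
        idx = [i for i, e in enumerate(hg.electrode_ids) if roi_map.get(e) == roi]
        if not idx:
            continue
        blocks.append(hg.values[:, idx, :].mean(axis=1))
        ids.append(np.asarray(hg.trial_index))
    if not blocks:
        return None
    return np.concatenate(ids), np.vstack(blocks)


def pooled_region_divergence(hg_by_participant: dict, trials: pd.DataFrame,
                             electrodes: pd.DataFrame,
                             cfg: DivergenceConfig | None = None) -> dict:
    """Four-condition ANOVA divergence per ROI, trials pooled across all
    participants' electrodes in that ROI (each trial x electrode is one
    observation)."""
    cfg = cfg or DivergenceConfig()
    roi_map = dict(zip(electrodes["electrode_id"], electrodes["roi"]))
    delay_of = dict(zip(trials["trial"], trials["delay_index"]))
    out = {}
    rois = sorted(set(roi_map.values()) - {"other"})
    any_hg = next(iter(hg_by_participant.values()))
    for roi in rois:
        X_parts, y_parts = [], []
        for hg in hg_by_participant.values():
            idx = [i for i, e in enumerate(hg.electrode_ids) if roi_map.get(e) == roi]
            labels = np.array([delay_of[int(t)] for t in hg.trial_index])
            for i in idx:
                X_parts.append(hg.values[:, i, :])
                y_parts.append(labels)
        if not X_parts:
            continue
        det = DivergenceDetector(test="anova_1way", alpha_point=cfg.alpha_point,
                                 q_fdr=cfg.q_fdr, min_run=cfg.min_run,
                                 time_step=cfg.time_step)
        out[roi] = det.fit(np.vstack(X_parts), np.concatenate(y_parts),
                           times=any_hg.times).result()
    return out


def _measure_durations(recs: dict, trials: pd.DataFrame, window_pad: float = 1.0) -> pd.DataFrame:
    rows = []
    for pid, rec in recs.items():
        mic = rec.aux["microphone"]
        tr = trials[trials["participant"] == pid]
        for _, row in tr.iterrows():
            i0 = int((row["speech_onset_s"] - 0.3) * rec.fs)
            i1 = int((row["speech_onset_s"] + row["duration_s"] + window_pad) * rec.fs)
            dur = articulation_duration(mic[max(i0, 0):min(i1, mic.size)], rec.fs)
            rows.append({"trial": int(row["trial"]), "participant": pid,
                         "delay_ms": int(row["delay_ms"]),
                         "stimulus_id": row["stimulus_id"],
                         "duration_s": dur})
    return pd.DataFrame(rows)


def run_all(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run every stage on a synthetic cohort and write all reports.

    ``config`` holds a ``synth`` block of shared :class:`SynthConfig` fields
    plus optional per-task ``word``/``sentence`` override blocks. Identical
    configurations rerun bit-identically for the deterministic stages.
    """
    t_start = time.time()
    config = config or DEMO_COHORT
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    base = dict(config.get("synth", {}))
    if seed is not None:
        base["seed"] = int(seed)
    manifest = {"config": config, "seed": base.get("seed", 0),
                "config_hash": dio.config_hash(config), "outputs": []}

    def save_table(df, name):
        dio.write_table(df, out / name)
        manifest["outputs"].append(name)

    results = {}
    cohorts = {}
    for task in ("word", "sentence"):
        cfg_d = {**base, **config.get(task, {}), "task": task}
        cfg = SynthConfig(**cfg_d)
        trials, electrodes, recs = generate_cohort(cfg)
        hg = {pid: compute_high_gamma(rec, trials, task) for pid, rec in recs.items()}
        cohorts[task] = {"cfg": cfg, "trials": trials, "electrodes": electrodes,
                         "recs": recs, "hg": hg}
        save_table(trials, f"trials_{task}.tsv")
        for pid, h in hg.items():
            name = f"hg_{task}_{pid}.h5"
            dio.write_high_gamma(h, out / name, provenance=manifest["config_hash"])
            manifest["outputs"].append(name)

    electrodes = assign_rois(cohorts["word"]["electrodes"])
    save_table(electrodes, "electrodes.tsv")

    # --- electrode selection per task, then the common set -----------------
    selections = {}
    for task in ("word", "sentence"):
        reports = []
        for pid, h in cohorts[task]["hg"].items():
            sel = ElectrodeSelector(SelectionCriteria()).fit(h, task=task)
            reports.append(sel.report_)
        rep = pd.concat(reports, ignore_index=True)
        selections[task] = rep
        save_table(rep, f"selection_{task}.tsv")
    common = intersect_task_selections(selections["word"], selections["sentence"])
    (out / "selection_common.json").write_text(json.dumps(common, indent=2))
    manifest["outputs"].append("selection_common.json")
    results["selection"] = common
    if not common["common"]:
        raise DafEcogError("selection produced no common electrodes")

    # --- rank-2 NMF clustering on the word task ----------------------------
    word_hg = list(cohorts["word"]["hg"].values())
    matrix = build_matrix(word_hg, common["common"])
    model = ResponseProfileNMF(n_components=2, n_restarts=10,
                               random_state=base.get("seed", 0)).fit(matrix)
    sem = label_clusters(model.H_, matrix.times, matrix.n_trials)
    clusters = pd.DataFrame({"electrode": matrix.row_index,
                             "cluster": model.labels_,
                             "label": [sem["labels"][c] for c in model.labels_]})
    save_table(clusters, "clusters.tsv")
    results["clustering"] = {"labels": sem["labels"],
                             "sizes": clusters["cluster"].value_counts().to_dict(),
                             "residual": model.residual_,
                             "onsets": sem["onsets"]}

    # --- DAF sensitivity per task and the paired comparison ----------------
    sens = {}
    for task in ("word", "sentence"):
        parts = [daf_sensitivity(h, cohorts[task]["trials"], task)
                 for h in cohorts[task]["hg"].values()]
        sens[task] = pd.concat(parts, ignore_index=True)
        save_table(sens[task], f"sensitivity_{task}.tsv")
    comparison = compare_task_sensitivity(sens["word"], sens["sentence"], electrodes)
    (out / "sensitivity_compare.json").write_text(json.dumps(comparison, indent=2))
    manifest["outputs"].append("sensitivity_compare.json")
    results["sensitivity"] = comparison
    results["sensitivity_tables"] = sens
    results["clusters_table"] = clusters

    # --- divergence onsets per region (sentence task) ----------------------
    div = pooled_region_divergence(cohorts["sentence"]["hg"],
                                   cohorts["sentence"]["trials"], electrodes)
    div_rows = [{"roi": roi, "onset_s": r.onset,
                 "runs": [list(run) for run in r.runs], "n": r.n_units}
                for roi, r in div.items()]
    (out / "divergence_sentence.json").write_text(json.dumps(div_rows, indent=2))
    manifest["outputs"].append("divergence_sentence.json")
    results["divergence"] = {row["roi"]: row for row in div_rows}

    # --- behavioral delay effect ------------------------------------------
    durations = _measure_durations(cohorts["sentence"]["recs"],
                                   cohorts["sentence"]["trials"])
    save_table(durations, "durations_sentence.tsv")
    beh = behavior_anova(durations)
    results["behavior"] = {"F": beh.f_delay, "df": beh.df_delay, "p": beh.p_delay,
                           "mean_by_delay": durations.groupby("delay_ms")["duration_s"]
                           .mean().to_dict()}
    (out / "behavior.json").write_text(json.dumps(results["behavior"], indent=2))
    manifest["outputs"].append("behavior.json")

    # --- warp-normalized 0 vs 200 ms contrast ------------------------------
    s = cohorts["sentence"]
    audio = {pid: rec.aux["microphone"] for pid, rec in s["recs"].items()}
    warp_reports = {}
    for pid, h in s["hg"].items():
        rep = warp_normalized_contrast(h, s["trials"], {pid: audio[pid]},
                                       electrodes, s["cfg"].sampling_rate)
        for roi, r in rep.items():
            warp_reports.setdefault(roi, []).append(r)
    warp_summary = {roi: {"onset_s": reps[0]["result"].onset,
                          "duration_t": reps[0]["duration_ttest"]}
                    for roi, reps in warp_reports.items()}
    (out / "warp_contrast.json").write_text(json.dumps(warp_summary, indent=2))
    manifest["outputs"].append("warp_contrast.json")
    results["warp"] = warp_summary

    # --- dissociation controls --------------------------------------------
    controls = {}
    tr_sent = s["trials"].copy()
    # pair within participant and stimulus
    tr_sent["stimulus_id"] = tr_sent["participant"] + ":" + tr_sent["stimulus_id"]
    matched = match_by_duration(tr_sent)
    controls["matched_n_pairs"] = len(matched.pairs)
    ctrl_roi = {}
    trial_rows = {}
    for roi in sorted(set(electrodes["roi"]) - {"other"}):
        rm = roi_trial_means(s["hg"], s["trials"], electrodes, roi)
        if rm is None:
            continue
        ids, R = rm
        posmap = {int(t): k for k, t in enumerate(ids)}
        entry = {}
        if matched.pairs:
            X = np.stack([[R[posmap[a]], R[posmap[b]]] for a, b in matched.pairs])
            det = DivergenceDetector(test="paired_t").fit(
                X, times=next(iter(s["hg"].values())).times)
            entry["matched_onset_s"] = det.onset_
        t200 = s["trials"][s["trials"]["delay_ms"] == max(s["cfg"].delays)]
        groups = percentile_split(t200["duration_s"].to_numpy(),
                                  t200["trial"].to_numpy())
        order = np.concatenate(groups)
        labels = np.concatenate([[g] * len(ids_) for g, ids_ in enumerate(groups)])
        times = next(iter(s["hg"].values())).times
        keep = (times >= -1e-9) & (times <= float(t200["duration_s"].min()) + 1e-9)
        det = DivergenceDetector(test="anova_1way").fit(
            np.stack([R[posmap[int(t)]] for t in order])[:, keep], labels,
            times=times[keep])
        entry["percentile_onset_s"] = det.onset_
        ctrl_roi[roi] = entry
    controls["by_roi"] = ctrl_roi
    (out / "controls.json").write_text(json.dumps(controls, indent=2))
    manifest["outputs"].append("controls.json")
    results["controls"] = controls

    manifest["elapsed_s"] = round(time.time() - t_start, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    results["manifest"] = manifest
    return results
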
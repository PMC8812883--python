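# daf-ecog

Analysis pipeline for electrocorticography (ECoG) recorded while people read
words and sentences aloud under **delayed auditory feedback (DAF)** — their
own voice played back through earphones with a 0/50/100/200 ms delay. DAF
slows articulation and enhances cortical responses in auditory regions; this
package quantifies where, when, and how strongly, and ships a synthetic-data
generator that plants exactly the structure the analysis assumes, so every
stage is testable without any recordings.

It is intended for speech-production electrophysiologists and methods
developers who want a reusable, tested implementation of this analysis
family (event-locked high-gamma pipelines with delay-sensitivity statistics).

## What it computes

1. **High-gamma responses.** Common average reference, zero-phase notches at
   60/120/180 Hz, speech-onset-locked epochs (−1.5…3.5 s words,
   −1.5…5.5 s sentences), multitaper time–frequency power (3 Slepian
   tapers, 10–200 Hz in 5-Hz steps, 200-ms windows every 10 ms, ±10 Hz
   smoothing), and percent signal change
   `100·(P(t) − B)/B` of 70–150 Hz power against a per-electrode baseline
   `B` pooled over all trials in the −500…−100 ms pre-stimulus window.
2. **Electrode selection.** Speech-responsive iff a one-sided unpaired
   t test of trial-mean response (pre-onset −0.5–0 s or post-onset
   0–0.5 s / 0–3 s window) against the −1…−0.6 s baseline gives
   p < 10⁻⁴ *and* μ/σ > 0.7 in the same window; electrodes common to both
   tasks carry forward.
3. **Response-profile clustering.** Rank-2 nonnegative matrix factorization
   `A ≈ W·H` of the electrode × (trial·time) matrix by multiplicative
   updates (best of restarts, monotone RMS residual); clusters labeled
   auditory-like vs motor-like by centroid onset relative to speech onset.
4. **DAF sensitivity.** Per electrode, the trial-wise Spearman correlation ρ
   between delay condition and window-mean response (0–1 s words, 0–3 s
   sentences), an OLS-slope variant, and an electrode-paired word-vs-sentence
   comparison.
5. **Divergence onsets.** Pointwise one-way ANOVA (or paired t) per 10-ms
   bin with Benjamini–Hochberg FDR (q = 0.05) and a run-length rule
   (p < 0.001 ANOVA / p < 0.01 pairwise for ≥ 200 consecutive ms), per
   region of interest (STG, SMG, vPreCG, dPreCG split at |MNI z| = 40,
   postCG, IFG).
6. **DTW warp normalization.** Per sentence stimulus, dynamic time warping
   aligns the no-delay and 200-ms speech envelopes; the warping path (not
   the neural data) maps 200-ms-condition neural trials onto the no-delay
   grid, so amplitude differences can be read without articulation-duration
   confounds; post-warp full-width-quarter-maximum durations verify the
   alignment.
7. **Dissociation controls.** (a) no-delay/200-ms trial pairs of the same
   stimulus matched in articulation duration to < 10 ms; (b) 200-ms trials
   split into duration quartiles; plus a delay-effect ANOVA on articulation
   durations with participant as a factor.

## Worked example

```python
from daf_ecog.pipeline import qualitative_reproduction

q = qualitative_reproduction(seed=10)
print(q["cluster_sizes"], round(q["accuracy"], 2))
print({t: {k: round(v, 2) for k, v in r.items()} for t, r in q["mean_rho"].items()})
print(round(q["paired"]["t"], 2), q["paired"]["p"])
```

prints (seed 10, two synthetic participants, 18 electrodes):

```
{'auditory-like': 8, 'motor-like': 10} 1.0
{'word': {'auditory-like': 0.76, 'motor-like': 0.17},
 'sentence': {'auditory-like': 0.9, 'motor-like': 0.75}}
6.77 3.2839900232072983e-06
```

Reading: NMF recovered the two planted response families perfectly (8
auditory-like, 10 motor-like electrodes). The auditory-like cluster is
strongly delay-sensitive in both tasks (mean ρ 0.76 / 0.90), the motor-like
cluster only during sentence reading (0.17 vs 0.75), and sentence
sensitivity exceeds word sensitivity electrode-wise (paired t = 6.8,
p ≈ 3×10⁻⁶) — the qualitative signature of auditory-feedback error
processing spreading into motor regions for long utterances.

The same cohort end to end, with all stage reports written to disk:

```bash
daf-ecog run-all --seed 10 --out runs/demo
```

## Layout

| module | contents |
|---|---|
| `daf_ecog.synth` | trial/electrode tables, envelope templates, 512-Hz recordings, fast-path responses, fixtures |
| `daf_ecog.preprocess` | CAR, notch, epoching, multitaper, percent change, FWQM |
| `daf_ecog.selection` | `ElectrodeSelector`, task intersection, ROI grouping |
| `daf_ecog.clustering` | `build_matrix`, `ResponseProfileNMF`, cluster semantics |
| `daf_ecog.sensitivity` | Spearman/slope indices, paired task comparison |
| `daf_ecog.divergence` | `DivergenceDetector`: pointwise tests + FDR + run length |
| `daf_ecog.warping` | speech envelopes, DTW, path transfer, warp contrast |
| `daf_ecog.behavior` | articulation durations, delay ANOVA, matching, quartiles |
| `daf_ecog.pipeline` / `daf_ecog.cli` | orchestration and the `daf-ecog` CLI |

See `docs/methods.md` for the model assumptions, parameter choices, and
known limitations.
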
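# Methods

## The measurement model

The pipeline treats 70–150 Hz ("high gamma") band power as a proxy for local
population activity. Each electrode's continuous voltage is re-referenced to
the common average (after excluding user-flagged bad channels), notch
filtered, epoched to speech onset, and decomposed with a multitaper
short-time estimator: 3 DPSS tapers on a fixed 200-ms window
(time–half-bandwidth product 2, i.e. ±10 Hz smoothing), evaluated at
10:5:200 Hz on an exact 10-ms output grid. Because 10 ms is 5.12 samples at
512 Hz, each output bin's window is centered on the nearest raw sample; bins
whose window would leave the epoch are reported missing (NaN), never
zero-padded, and every downstream statistic skips missing bins.

Band power is averaged over 70–150 Hz first and then normalized per
electrode to percent signal change against a baseline pooled across **all**
trials in the −500…−100 ms window before **stimulus** onset (the epochs used
for analysis are speech-locked; the baseline is computed from a separate
stimulus-locked epoching pass). Pooling the baseline across trials makes the
normalization a single per-electrode constant, so percent change is exactly
invariant to global gain and a constant-power signal maps to 0%.

Known estimator bias: the notch at 120 Hz sits inside the 70–150 Hz band,
and the band edges plus the ±10 Hz smoothing clip part of a broadband
burst's power, so recovered percent change underestimates a planted
amplitude by roughly 10–15% uniformly across conditions. The common average
reference also leaks a small, delay-dependent fraction (~1/N² per source
electrode) of strong auditory responses into other channels. Both effects
are multiplicative or small and cancel in the ratio/rank statistics the
pipeline reports; tests on planted amplitudes therefore check gain *ratios*
(to 20% relative, reflecting the carrier-realization variance at the tested
trial counts) and rank correlations, not absolute percent values.

## Statistics

* **Selection** uses per-trial window means as the unit of observation: a
  one-sided unpaired t test (window vs baseline means across trials) at
  p < 10⁻⁴, gated by μ/σ > 0.7 computed across the same window means. The
  gate must pass in a window that also passes the t test. The sidedness
  follows from the criterion being a response *increase*; a two-sided switch
  exists.
* **Clustering** factorizes the electrode × (trial·time) matrix (word task,
  all delays) with rank-2 NMF. Negative percent-change entries are clipped
  to zero (speech high-gamma responses are overwhelmingly positive; the
  clipped count is recorded; a min-shift alternative is a config choice we
  did not take because it inflates the flat baseline into the factors).
  Multiplicative updates guarantee a non-increasing RMS residual, which the
  test suite asserts on every fitted trace; ten seeded restarts guard
  against local minima, keeping the best final residual. Electrodes join the
  cluster of their largest loading after the components are normalized to
  unit energy (ties, which require exact float equality, go to the lower
  index). Semantic labels come from centroid onsets (first crossing of 25%
  of the centroid's peak): the earlier-onset component — rising before
  speech onset — is motor-like.
* **Sensitivity** is the Spearman correlation between delay condition and
  window-mean response, computed explicitly as the Pearson correlation of
  average ranks so that tie handling is transparent; constant responses get
  ρ = 0 with a degeneracy flag rather than NaN. Delay may be encoded as
  ordinal index or raw milliseconds — rank invariance makes the two
  identical, and the suite asserts it.
* **Divergence** runs a pointwise one-way ANOVA (trials pooled across a
  region's electrodes, each trial × electrode an observation) or a paired t
  test per 10-ms bin, corrects across bins with Benjamini–Hochberg at
  q = 0.05 (within region; correcting across regions jointly is a
  configuration choice), and reports maximal runs where the pointwise p also
  beats 0.001 (ANOVA) or 0.01 (pairwise) for at least 20 consecutive bins.
  A 20-bin run spans exactly 0.200 s under the half-open bin convention.
  The onset is the earliest qualifying run's start.
* **Warp normalization** aligns, per sentence stimulus, the trial-averaged
  no-delay and 200-ms speech envelopes with DTW (absolute-difference local
  cost, steps {(1,0),(0,1),(1,1)}, boundary constrained, ties preferring the
  diagonal so paths are deterministic; no band constraint — sequences are a
  few hundred bins). The path maps each 200-ms neural trial onto the
  no-delay grid, collapsing many-to-one by arithmetic mean (unbiased under
  local stationarity). Trial averages per stimulus then enter the paired-t
  divergence pipeline (pairing by stimulus), and FWQM durations before/after
  warping quantify alignment.
* **Controls.** Duration matching pairs no-delay and 200-ms trials of the
  same stimulus with |Δduration| < 10 ms (strict), via a sorted two-pointer
  sweep per stimulus — optimal for threshold compatibility on a line, and
  verified against a brute-force bipartite oracle in the tests. The quartile
  split uses linear-interpolation percentiles with half-open groups, ties to
  the lower group. The quartile ANOVA is restricted to bins before the
  shortest included articulation ends: beyond that point short-duration
  trials' responses have simply ended, and a "divergence" there would only
  restate the duration difference rather than an amplitude effect.
* **Behavioral ANOVA** is a fixed-effects two-factor model
  (delay + participant, no interaction) on per-trial articulation durations;
  the participant factor absorbs between-speaker baseline differences in
  lieu of a random-effects model, which at these cohort sizes changes
  nothing about the delay F test.

## The synthetic generator

The generator emulates exactly the features the analysis exploits:

* Two response archetypes as percent-change envelopes locked to speech
  onset: auditory (onset 0 s, peak 0.32 s, 115%) and motor (onset −0.75 s,
  peak 0.14 s, 60%), with raised-cosine rise/decay and a plateau that
  stretches with articulation duration while onset and peak latencies stay
  fixed — so delay lengthens responses without moving their onsets.
* Delay-dependent amplitude gains per archetype (defaults 1/1.2/1.4/1.8 for
  auditory, flat for motor), optionally applied only after a planted
  post-onset time (divergence plants), or driven by articulation duration
  instead of delay (control-dissociation plants).
* Articulation durations `base + slope·delay_index + noise`, defaulting to
  the published means (0.698→0.749 s words, 2.761→3.418 s sentences; the
  word values are printed as "milliseconds" in the source but are plainly
  seconds). Trial-duration noise defaults to 50 ms; cohorts meant for
  duration-matching use 0.35 s, a realistic between-trial spread without
  which sub-10-ms matches would not exist at desk-scale trial counts.
* Two render paths. The **full path** synthesizes 512-Hz recordings: pink
  background, 70–150 Hz band-limited noise carriers amplitude-modulated so
  the in-band power increase equals the planted percent change,
  60/120/180 Hz line sinusoids, and auxiliary trigger/microphone/feedback
  channels (feedback = microphone shifted by the delay, rounded to whole
  samples). The **fast path** emits percent-change responses directly on the
  10-ms grid with white Gaussian bin noise (default SD 10, in percent-change
  units), and is what the Monte-Carlo calibrations use; the full path is
  exercised by the end-to-end reproduction and the spectral-recovery tests.
* One RNG stream per (participant, purpose) derived from the master seed:
  adding participants never perturbs earlier ones, and identical
  configurations are bit-identical.
* 10 word / 6 sentence envelope templates (syllable-rate bump trains,
  seeded per stimulus) that stretch with articulation duration; trials are
  laid out with at least a 1-s inter-trial interval and no epoch overlap.

What the generator does **not** emulate: epileptiform or movement artifacts,
electrode drift, correlated noise across electrodes, real acoustic
structure (envelopes only, no formants), speech errors, or heterogeneous
per-electrode response shapes within an archetype. Passing tests therefore
demonstrate that the *methods* recover planted structure under realistic
noise levels and confound geometry — not that real cortical data satisfy the
generator's assumptions.

## Study-scale choices

Desk-scale problem sizes are deliberate package defaults: demo cohorts use
2 participants × 18 electrodes × 10 trials per delay (full signal path), and
the calibrations use 40 trials/condition for divergence recovery, 36 for the
control dissociations, 6 sentence stimuli × 3 trials/cell for warping, and
4 participants × 12 trials/delay for the behavioral ANOVA. The delay effect
in the word-task motor cluster is assessed primarily through the
sensitivity index rather than a pooled-trial ANOVA: at pooled n the ANOVA
resolves even the few-percent effects that the plant necessarily contains
(articulation-duration elongation plus reference leakage), while the mean
sensitivity index cleanly separates the planted-sensitive cells (ρ ≈ 0.75–0.9)
from the insensitive one (ρ ≈ 0.1–0.2).

## Numerical conventions

Half-open time bins ([t, t+10 ms), time 0 at the locking event); FWQM
crossings located by linear interpolation, NaN for non-positive curves; NMF
convergence at relative residual change < 10⁻⁶ (500-iteration cap, best-so-far
returned with a warning trace on non-convergence); Spearman degenerate
inputs → 0; paired tests with exactly zero-variance differences report
t = ±∞ with p = 0 (or t = 0, p = 1 for identical inputs); BH-FDR treats NaN
bins as outside the family. EDF is read through mne when available; all
array outputs persist to HDF5, tables to TSV, configs to JSON/YAML.

## Limitations

* The anatomical grouping consumes already-localized MNI coordinates and
  FreeSurfer labels; no imaging is performed.
* Only CAR referencing and list-based electrode exclusion are provided.
* The auditory-error regressor variant of the sensitivity analysis is not
  implemented (its construction is not specified in the available text).
* DTW transfer is pairwise (no-delay vs 200 ms); no multi-condition joint
  alignment.
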
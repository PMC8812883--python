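"""Configuration dataclasses for synthesis, selection, and divergence tests.

Defaults mirror the reference delayed-auditory-feedback (DAF) reading
experiment: feedback delays of 0/50/100/200 ms, 512 Hz acquisition, word and
sentence reading tasks, and the published analysis thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .exceptions import ConfigurationError

__all__ = ["ResponseArchetype", "SynthConfig", "SelectionCriteria", "DivergenceConfig",
           "DEFAULT_AUDITORY", "DEFAULT_MOTOR", "AUDITORY_ROIS", "MOTOR_ROIS"]

#: ROIs whose synthetic electrodes follow the auditory vs motor archetype.
AUDITORY_ROIS = ("STG", "SMG")
MOTOR_ROIS = ("vPreCG", "dPreCG", "postCG", "IFG")


@dataclass(frozen=True)
class ResponseArchetype:
    """Canonical high-gamma response shape of one electrode class.

    ``onset``/``peak_time`` are seconds relative to speech onset; auditory
    responses begin at or after speech onset and peak ~320 ms later, motor
    responses begin ~750 ms before speech onset. ``peak_amplitude`` is in
    percent change; the response sustains near its peak until articulation
    ends, then decays over ``decay`` seconds.
    """

    kind: str
    onset: float
    peak_time: float
    peak_amplitude: float
    decay: float = 0.3

    def __post_init__(self):
        if self.kind not in ("auditory", "motor"):
            raise ConfigurationError(f"archetype kind must be auditory|motor, got {self.kind!r}")
        if self.peak_amplitude < 0:
            raise ConfigurationError("peak_amplitude must be >= 0")
        if self.peak_time <= self.onset:
            raise ConfigurationError("peak_time must exceed onset")
        if self.kind == "auditory" and self.onset < 0:
            raise ConfigurationError("auditory archetype onset must be >= 0")
        if self.kind == "motor" and self.onset >= 0:
            raise ConfigurationError("motor archetype onset must be < 0")


DEFAULT_AUDITORY = ResponseArchetype("auditory", onset=0.0, peak_time=0.32,
                                     peak_amplitude=115.0, decay=0.3)
DEFAULT_MOTOR = ResponseArchetype("motor", onset=-0.75, peak_time=0.14,
                                  peak_amplitude=60.0, decay=0.3)

#: Stimulus inventory per task: 10 three-syllable words, 6 eight-word sentences.
N_STIMULI = {"word": 10, "sentence": 6}
#: Speech-locked epoch extents (seconds) per task.
EPOCH_WINDOWS = {"word": (-1.5, 3.5), "sentence": (-1.5, 5.5)}
#: Post-onset analysis window for selection per task.
POST_WINDOWS = {"word": (0.0, 0.5), "sentence": (0.0, 3.0)}
#: Sensitivity-index averaging window per task.
SENSITIVITY_WINDOWS = {"word": (0.0, 1.0), "sentence": (0.0, 3.0)}


@dataclass
class SynthConfig:
    """Synthetic DAF cohort configuration.

    Amplitude gains are unitless multipliers of the archetype's percent-change
    envelope, one per delay level; articulation duration is
    ``duration_base + duration_slope * delay_index`` plus trial noise,
    truncated positive. ``noise_sd`` is trial-to-trial additive noise in
    percent-change units on the 10-ms response grid.
    """

    n_participants: int = 2
    n_electrodes_per_roi: dict = field(default_factory=lambda: {
        "STG": 3, "SMG": 1, "vPreCG": 2, "dPreCG": 1, "postCG": 1, "IFG": 1})
    task: str = "word"
    n_trials_per_delay: int = 18
    delays: tuple = (0, 50, 100, 200)
    sampling_rate: float = 512.0
    auditory_gain_per_delay: tuple = (1.0, 1.2, 1.4, 1.8)
    motor_gain_per_delay: tuple = (1.0, 1.0, 1.0, 1.0)
    duration_base: float | None = None     # default per task below
    duration_slope: float | None = None
    duration_noise_sd: float = 0.05
    noise_sd: float = 10.0
    speech_latency: float = 0.75           # stimulus onset -> speech onset, s
    iti: float = 1.5                       # inter-trial interval, >= 1 s
    seed: int = 0

    #: word/sentence defaults follow the published mean articulation durations
    #: (0.698->0.749 s across delays for words, 2.761->3.418 s for sentences).
    _DURATION_DEFAULTS = {
        "word": (0.698, 0.017),
        "sentence": (2.761, 0.219),
    }

    def __post_init__(self):
        if self.task not in ("word", "sentence"):
            raise ConfigurationError(f"task must be word|sentence, got {self.task!r}")
        if self.duration_base is None:
            self.duration_base = self._DURATION_DEFAULTS[self.task][0]
        if self.duration_slope is None:
            self.duration_slope = self._DURATION_DEFAULTS[self.task][1]
        self.delays = tuple(int(d) for d in self.delays)
        if len(self.delays) < 2 or any(b <= a for a, b in zip(self.delays, self.delays[1:])):
            raise ConfigurationError("delays must be strictly increasing")
        if self.delays[0] != 0:
            raise ConfigurationError("delays[0] must be 0 (no-delay condition)")
        if self.n_trials_per_delay < 2:
            raise ConfigurationError("n_trials_per_delay must be >= 2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.duration_noise_sd < 0:
            raise ConfigurationError("duration_noise_sd must be >= 0")
        if self.n_participants < 1:
            raise ConfigurationError("n_participants must be >= 1")
        if self.sampling_rate <= 2 * 180.0:
            # highest synthesized frequency: 180 Hz line-noise harmonic
            raise ConfigurationError("sampling_rate must exceed twice the highest synthesized frequency (180 Hz)")
        if len(self.auditory_gain_per_delay) != len(self.delays):
            raise ConfigurationError("auditory_gain_per_delay must have one gain per delay")
        if len(self.motor_gain_per_delay) != len(self.delays):
            raise ConfigurationError("motor_gain_per_delay must have one gain per delay")
        if self.iti < 1.0:
            raise ConfigurationError("iti must be >= 1 s")
        roi_counts = dict(self.n_electrodes_per_roi)
        unknown = set(roi_counts) - set(AUDITORY_ROIS) - set(MOTOR_ROIS)
        if unknown:
            raise ConfigurationError(f"n_electrodes_per_roi has unknown ROIs: {sorted(unknown)}")
        self.n_electrodes_per_roi = roi_counts

    @property
    def n_delays(self) -> int:
        return len(self.delays)

    @property
    def n_trials(self) -> int:
        return self.n_delays * self.n_trials_per_delay

    @property
    def epoch_window(self) -> tuple:
        return EPOCH_WINDOWS[self.task]

    @property
    def n_stimuli(self) -> int:
        return N_STIMULI[self.task]

    def gains_for(self, archetype_kind: str) -> np.ndarray:
        g = (self.auditory_gain_per_delay if archetype_kind == "auditory"
             else self.motor_gain_per_delay)
        return np.asarray(g, dtype=float)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class SelectionCriteria:
    """Dual statistical/SNR electrode-selection criterion.

    An electrode is speech-responsive when its trial-mean percent change in
    the pre-onset (-0.5..0 s) or post-onset window shows a significant
    increase over the -1..-0.6 s baseline (one-sided unpaired t test,
    p < 1e-4) and the same window has mean/SD > 0.7 across trials.
    """

    p_threshold: float = 1e-4
    snr_threshold: float = 0.7
    pre_window: tuple = (-0.5, 0.0)
    post_window_word: tuple = POST_WINDOWS["word"]
    post_window_sentence: tuple = POST_WINDOWS["sentence"]
    baseline_window: tuple = (-1.0, -0.6)
    two_sided: bool = False

    def __post_init__(self):
        if not (0 < self.p_threshold < 1):
            raise ConfigurationError("p_threshold must be in (0, 1)")
        if self.snr_threshold <= 0:
            raise ConfigurationError("snr_threshold must be > 0")
        for w in (self.pre_window, self.post_window_word, self.post_window_sentence):
            if not (w[0] < w[1]):
                raise ConfigurationError("windows must satisfy t0 < t1")
            if w[0] < self.baseline_window[1] < w[1] or w[0] < self.baseline_window[0] < w[1]:
                raise ConfigurationError("analysis windows must not overlap the baseline window")

    def post_window(self, task: str) -> tuple:
        return self.post_window_word if task == "word" else self.post_window_sentence


@dataclass
class DivergenceConfig:
    """Pointwise-test + FDR + run-length divergence criterion.

    4-condition one-way ANOVA uses alpha_point = 0.001; pairwise (paired-t)
    contrasts use 0.01. Benjamini-Hochberg FDR at q = 0.05 across time bins;
    significance must persist for at least 200 consecutive milliseconds on
    the 10-ms grid (20 bins).
    """

    test: str = "anova_1way"
    alpha_point: float | None = None
    q_fdr: float = 0.05
    min_run: float = 0.200
    time_step: float = 0.010

    def __post_init__(self):
        if self.test not in ("anova_1way", "paired_t"):
            raise ConfigurationError(f"test must be anova_1way|paired_t, got {self.test!r}")
        if self.alpha_point is None:
            self.alpha_point = 0.001 if self.test == "anova_1way" else 0.01
        if not (0 < self.alpha_point < 1):
            raise ConfigurationError("alpha_point must be in (0, 1)")
        if not (0 < self.q_fdr < 1):
            raise ConfigurationError("q_fdr must be in (0, 1)")
        ratio = self.min_run / self.time_step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ConfigurationError("min_run must be an integer multiple of time_step")

    @property
    def min_run_bins(self) -> int:
        return int(round(self.min_run / self.time_step))
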
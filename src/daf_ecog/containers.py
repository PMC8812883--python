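"""Core in-memory containers for the DAF-ECoG pipeline.

Tabular data (trial tables, electrode tables, selection reports) are plain
:class:`pandas.DataFrame` objects with documented column sets; array-shaped
data travel in the lightweight dataclasses below.

Trial-table columns
    ``trial`` (int, unique), ``participant`` (str), ``task`` ({"word",
    "sentence"}), ``stimulus_id`` (str), ``delay_ms`` (int), ``delay_index``
    (int, ordinal 0..n_delays-1), ``stimulus_onset_s``, ``speech_onset_s``,
    ``duration_s`` (articulation duration, seconds).

Electrode-table columns
    ``electrode_id`` (str, unique), ``participant``, ``mni_x/mni_y/mni_z``
    (mm), ``fs_label`` (FreeSurfer cortical label), ``roi`` (derived),
    and for synthetic cohorts ``archetype`` ({"auditory", "motor"}).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RawRecording",
    "EpochSet",
    "TimeFrequencyPower",
    "HighGammaResponse",
    "ResponseMatrix",
    "DivergenceResult",
    "WarpPath",
    "MatchedPairs",
    "BehaviorResult",
]


@dataclass
class RawRecording:
    """Continuous multichannel recording with auxiliary channels.

    Attributes
    ----------
    signals : ndarray, shape (n_electrodes, n_samples)
        Voltage-like ECoG traces.
    fs : float
        Sampling rate in Hz (512 for the reference acquisition).
    electrode_ids : list of str
        Row labels of ``signals``.
    aux : dict of str -> ndarray
        Auxiliary channels on the same sample clock: ``trigger`` (impulses at
        stimulus and speech onsets), ``microphone`` (speech envelope), and
        ``feedback`` (microphone delayed by the trial's feedback delay).
    participant : str
    """

    signals: np.ndarray
    fs: float
    electrode_ids: list
    aux: dict = field(default_factory=dict)
    participant: str = ""

    def __post_init__(self) -> None:
        self.signals = np.asarray(self.signals, dtype=float)
        if self.signals.ndim != 2:
            raise ValueError("signals must be 2-D (electrodes x samples)")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        n = self.signals.shape[1]
        for name, ch in self.aux.items():
            if len(ch) != n:
                raise ValueError(f"aux channel {name!r} length differs from signals")

    @property
    def n_electrodes(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Event-locked epochs: trials x electrodes x samples at the raw rate."""

    data: np.ndarray
    time_axis: np.ndarray
    fs: float
    window: tuple
    trial_index: np.ndarray
    electrode_ids: list
    lock: str = "speech_onset"

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class TimeFrequencyPower:
    """Multitaper power: trials x electrodes x frequencies x time bins.

    Bins whose 200-ms estimation window exceeds the epoch are NaN, never
    zero-padded.
    """

    power: np.ndarray
    freqs: np.ndarray
    times: np.ndarray
    trial_index: np.ndarray
    electrode_ids: list
    lock: str = "speech_onset"


@dataclass
class HighGammaResponse:
    """Percent-change high-gamma (70-150 Hz) responses on a 10-ms grid.

    ``values`` is trials x electrodes x time bins, in percent signal change
    relative to a per-electrode baseline power pooled over all trials
    (baseline window -500..-100 ms before stimulus onset). A constant-power
    signal maps to 0% everywhere.
    """

    values: np.ndarray
    times: np.ndarray
    trial_index: np.ndarray
    electrode_ids: list
    task: str = "word"
    time_step: float = 0.010
    baseline_window: tuple = (-0.5, -0.1)
    baseline_power: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.trial_index = np.asarray(self.trial_index)

    @property
    def n_trials(self) -> int:
        return self.values.shape[0]

    @property
    def n_electrodes(self) -> int:
        return self.values.shape[1]

    def electrode_index(self, electrode_id) -> int:
        return list(self.electrode_ids).index(electrode_id)

    def window_mask(self, window: tuple) -> np.ndarray:
        """Boolean mask over time bins for half-open window [t0, t1)."""
        t0, t1 = window
        return (self.times >= t0 - 1e-9) & (self.times < t1 - 1e-9)


@dataclass
class ResponseMatrix:
    """Electrode-by-time matrix for factorization.

    Rows are selected electrodes (across participants); columns concatenate
    per-trial 10-ms time courses. Negative percent-change entries have been
    clipped to zero (``n_clipped`` counts them).
    """

    A: np.ndarray
    row_index: list
    col_index: list
    n_trials: int
    n_bins: int
    times: np.ndarray
    n_clipped: int = 0


@dataclass
class DivergenceResult:
    """Per-timepoint divergence statistics for one region/contrast.

    ``runs`` are half-open (start_s, end_s) intervals during which the
    pointwise p-value beats ``alpha_point`` inside the FDR-passing set for at
    least the minimum run length; ``onset`` is the start of the earliest run
    (None when no run qualifies).
    """

    statistic_series: np.ndarray
    p_series: np.ndarray
    fdr_mask: np.ndarray
    runs: list
    onset: float | None
    times: np.ndarray
    test: str = "anova_1way"
    n_units: int = 0


@dataclass
class WarpPath:
    """Monotone DTW warping path between two sequences.

    ``pairs`` is an ordered (L, 2) integer array of 0-based (i, j) index
    pairs, starting at (0, 0) and ending at (N-1, M-1); steps are from
    {(1, 0), (0, 1), (1, 1)}. ``cost`` is the accumulated absolute-difference
    distance along the path.
    """

    pairs: np.ndarray
    cost: float
    n_source: int
    n_target: int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int)

    def target_bins_for_source(self) -> list:
        """For each source bin i, the list of target bins j with (i, j) on the path."""
        out = [[] for _ in range(self.n_source)]
        for i, j in self.pairs:
            out[i].append(j)
        return out


@dataclass
class MatchedPairs:
    """Duration-matched (no-delay, 200-ms) trial pairs within stimulus."""

    pairs: list  # list of (trial_no_delay, trial_200ms)
    n_unmatched: int
    tolerance: float = 0.010


@dataclass
class BehaviorResult:
    """Articulation-duration summary and delay-effect ANOVA."""

    durations: "object"  # DataFrame: trial, participant, delay_ms, duration_s
    cell_means: "object"  # DataFrame: participant x delay mean durations
    f_delay: float
    df_delay: tuple
    p_delay: float
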
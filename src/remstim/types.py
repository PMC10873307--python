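"""Core containers shared across the pipeline.

Time is expressed in seconds from the start of the recording; voltages in
microvolts. Sleep stages follow AASM labels (W, N1, N2, N3, R) scored in
fixed 30-s epochs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

STAGES = ("W", "N1", "N2", "N3", "R")
EPOCH_LEN_S = 30.0


@dataclass
class Hypnogram:
    """Per-epoch sleep staging with arousal/artifact annotations.

    ``stages`` holds one AASM label per 30-s epoch. ``arousals`` and
    ``artifacts`` are (onset_s, duration_s) intervals relative to
    ``record_start_s``.
    """

    stages: list[str]
    arousals: list[tuple[float, float]] = field(default_factory=list)
    artifacts: list[tuple[float, float]] = field(default_factory=list)
    record_start_s: float = 0.0
    epoch_len_s: float = EPOCH_LEN_S

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stage labels: {sorted(bad)}")
        dur = self.duration_s
        for name, ivals in (("arousal", self.arousals), ("artifact", self.artifacts)):
            for onset, length in ivals:
                if length < 0 or onset < 0 or onset + length > dur + 1e-9:
                    raise ValueError(f"{name} interval ({onset}, {length}) outside record")

    @property
    def n_epochs(self) -> int:
        return len(self.stages)

    @property
    def duration_s(self) -> float:
        return self.n_epochs * self.epoch_len_s

    def stage_at(self, t_s: float) -> str:
        """Stage of the epoch containing time ``t_s`` (record-relative)."""
        idx = int(t_s // self.epoch_len_s)
        if not 0 <= idx < self.n_epochs:
            raise ValueError(f"time {t_s} s outside hypnogram")
        return self.stages[idx]

    def epoch_bounds(self, idx: int) -> tuple[float, float]:
        return idx * self.epoch_len_s, (idx + 1) * self.epoch_len_s

    def rem_segments(self) -> list[tuple[int, int]]:
        """Maximal runs of R epochs as (first_epoch, last_epoch) inclusive."""
        segs, start = [], None
        for i, s in enumerate(self.stages):
            if s == "R" and start is None:
                start = i
            elif s != "R" and start is not None:
                segs.append((start, i - 1))
                start = None
        if start is not None:
            segs.append((start, self.n_epochs - 1))
        return segs


@dataclass
class SignalRecord:
    """One channel of polysomnography: samples in µV at a fixed rate."""

    label: str
    kind: str  # EEG | EOG | EMG
    fs: float
    samples: np.ndarray
    start_s: float = 0.0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        self.samples = np.asarray(self.samples, dtype=float)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.kind not in ("EEG", "EOG", "EMG"):
            raise ValueError(f"unknown signal kind {self.kind!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        return self.start_s + np.arange(self.n_samples) / self.fs


@dataclass
class Event:
    t_s: float
    type: str  # em_detected | click | stim_on | stim_off
    stage: str = ""
    muted: bool = False
    meta: dict = field(default_factory=dict)


@dataclass
class EventLog:
    """Time-ordered log from the closed-loop stimulator."""

    events: list[Event] = field(default_factory=list)

    def __post_init__(self) -> None:
        times = [e.t_s for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise ValueError("events must be time-ordered")

    def of_type(self, *types: str) -> list[Event]:
        return [e for e in self.events if e.type in types]

    def click_times(self) -> np.ndarray:
        return np.array([e.t_s for e in self.events if e.type == "click"])


@dataclass
class SyntheticGroundTruth:
    """Everything the generators injected, for downstream recovery checks."""

    em_times_s: np.ndarray = field(default_factory=lambda: np.array([]))
    p2_latency_s: float = 0.275
    p2_amplitude_uv: float = 6.0
    negativity_window_s: tuple[float, float] = (0.5, 1.5)
    negativity_amplitude_uv: float = -3.0
    beta_band_hz: tuple[float, float] = (15.0, 25.0)
    beta_window_s: tuple[float, float] = (0.2, 1.4)
    beta_amplitude_db: float = 1.0
    theta_band_hz: tuple[float, float] = (4.0, 8.0)
    theta_window_s: tuple[float, float] = (0.7, 1.5)
    theta_amplitude_db: float = -1.0
    behavioural_effects: dict = field(default_factory=dict)
    seed: int = 0


@dataclass
class BehaviouralSession:
    """One task session (pre- or post-sleep) for one subject and condition."""

    task: str  # PVT | VDT | MTT
    subject_id: str
    condition: str  # CNT | STM
    session: str  # pre | post
    trials: "object"  # pandas.DataFrame with task-specific columns


@dataclass
class SleepSummary:
    recording_min: float
    tst_min: float
    stage_pct: dict
    latency_min: float
    waso_min: float
    efficiency_pct: float
    arousal_count: int
    n_rem_segments: int
    em_density_per_min: float | None = None
    phasic_pct: float | None = None
    tonic_pct: float | None = None
    empty: bool = False


@dataclass
class RegressionFit:
    coefficients: np.ndarray
    std_errors: np.ndarray
    p_values: np.ndarray
    r_squared: float
    f_statistic: float
    f_pvalue: float
    df: tuple[int, int]
    n: int
    method: str  # OLS | Huber
    converged: bool = True


@dataclass
class PairedComparison:
    test: str  # paired_t | wilcoxon_signed_rank
    statistic: float
    p_value: float
    cohens_d: float
    normality_w: float
    normality_p: float
    transform: str = "none"
    degenerate: bool = False


@dataclass
class TaskScore:
    task: str
    subject_id: str
    condition: str
    session: str
    value: float
    n_valid_trials: int
    flagged: bool = False
    fit_diagnostics: dict = field(default_factory=dict)


@dataclass
class StimulatorConfig:
    """Tunables of the online eye-movement-locked stimulator."""

    threshold_uv: float = 75.0
    click_delay_s: float = 0.100
    refractory_s: float = 2.0
    muted: bool = False
    fs: float = 500.0

    def __post_init__(self) -> None:
        if self.threshold_uv <= 0 or self.refractory_s <= 0 or self.click_delay_s < 0:
            raise ValueError("invalid stimulator configuration")
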
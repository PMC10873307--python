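"""Sleep-architecture summaries, offline eye-movement detection, and
phasic/tonic REM classification.

Definitions: total sleep duration spans the first wake-to-sleep transition
to the last sleep-to-wake transition; total sleep time (TST) is time in any
non-wake stage; WASO is wake inside that span; stage percentages are of
TST; sleep efficiency is TST as a percentage of total sleep duration.
REM epochs with at least one eye-movement onset are phasic, the rest tonic.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .filters import apply_filter, design_named
from .types import EPOCH_LEN_S, Hypnogram, SignalRecord, SleepSummary


@dataclass
class EmEvent:
    onset_s: float
    peak_uv: float


def sleep_summary(hypnogram: Hypnogram, em_events: list[EmEvent] | None = None
                  ) -> SleepSummary:
    """Table-1-style sleep summary from a scored hypnogram."""
    stages = np.array(hypnogram.stages)
    e = hypnogram.epoch_len_s / 60.0  # epoch length in minutes
    recording_min = hypnogram.n_epochs * e
    sleep_idx = np.flatnonzero(stages != "W")
    if sleep_idx.size == 0:
        return SleepSummary(recording_min=recording_min, tst_min=0.0,
                            stage_pct={}, latency_min=float("nan"),
                            waso_min=0.0, efficiency_pct=float("nan"),
                            arousal_count=len(hypnogram.arousals),
                            n_rem_segments=0, empty=True)
    first, last = sleep_idx[0], sleep_idx[-1]
    span = stages[first:last + 1]
    duration_min = span.size * e                       # total sleep duration
    tst_min = float(np.sum(span != "W")) * e
    waso_min = float(np.sum(span == "W")) * e
    latency_min = first * e
    pct = {}
    for s in ("N1", "N2", "N3", "R"):
        pct[s if s != "R" else "REM"] = 100.0 * np.sum(span == s) * e / tst_min
    pct["NREM"] = pct["N2"] + pct["N3"]                # N2 and N3 only
    segs = hypnogram.rem_segments()

    summary = SleepSummary(
        recording_min=recording_min, tst_min=tst_min, stage_pct=pct,
        latency_min=latency_min, waso_min=waso_min,
        efficiency_pct=100.0 * tst_min / duration_min,
        arousal_count=len(hypnogram.arousals), n_rem_segments=len(segs))

    if em_events is not None:
        labels = classify_rem_epochs(hypnogram, em_events)
        rem_epochs = sum(1 for s in stages if s == "R")
        if rem_epochs and tst_min > 0:
            phasic = sum(1 for v in labels.values() if v == "phasic")
            tonic = rem_epochs - phasic
            summary.phasic_pct = 100.0 * phasic * e / tst_min
            summary.tonic_pct = 100.0 * tonic * e / tst_min
        stats = em_statistics(em_events, [], hypnogram)
        summary.em_density_per_min = stats["em_density_per_min"]
    return summary


def detect_em_offline(eog: SignalRecord, hypnogram: Hypnogram,
                      threshold_uv: float = 50.0,
                      refractory_s: float = 0.5,
                      prefiltered: bool = False) -> list[EmEvent]:
    """Offline eye-movement detection: the online threshold rule applied to
    the zero-phase offline EOG filter output, restricted to R epochs.

    A 0.5-s refractory prevents one biphasic saccade from being counted
    twice. Peak amplitude is the absolute maximum inside the refractory
    window after the crossing.
    """
    if not 0 < threshold_uv <= 500:
        raise ValueError("threshold must lie in (0, 500] µV")
    x = eog.samples if prefiltered else apply_filter(
        design_named("offline_eog", eog.fs), eog).samples
    fs = eog.fs
    above = np.abs(x) >= threshold_uv
    events: list[EmEvent] = []
    i = 0
    n = x.size
    hop = max(int(round(refractory_s * fs)), 1)
    while i < n:
        if above[i]:
            t = i / fs
            if t < hypnogram.duration_s and hypnogram.stage_at(t) == "R":
                peak = float(np.max(np.abs(x[i:i + hop])))
                events.append(EmEvent(onset_s=t, peak_uv=peak))
            i += hop
        else:
            i += 1
    return events


def classify_rem_epochs(hypnogram: Hypnogram, em_events: list[EmEvent]
                        ) -> dict[int, str]:
    """Label each R epoch phasic (>=1 EM onset inside) or tonic."""
    onsets = np.array([ev.onset_s for ev in em_events])
    if onsets.size and np.any(np.diff(onsets) < 0):
        raise ValueError("events must be time-sorted")
    labels: dict[int, str] = {}
    for i, stage in enumerate(hypnogram.stages):
        if stage != "R":
            continue
        t0, t1 = hypnogram.epoch_bounds(i)
        has_em = bool(onsets.size) and bool(np.any((onsets >= t0) & (onsets < t1)))
        labels[i] = "phasic" if has_em else "tonic"
    return labels


def em_statistics(em_events: list[EmEvent], click_times,
                  hypnogram: Hypnogram, window_s: float = 2.5) -> dict:
    """EM density, mean inter-EM interval (within REM segments), probability
    of an EM within ``window_s`` after a click, and the total count."""
    onsets = np.array([ev.onset_s for ev in em_events])
    clicks = np.asarray(click_times, dtype=float)
    rem_min = sum(1 for s in hypnogram.stages if s == "R") * hypnogram.epoch_len_s / 60.0

    out = {"total_em": int(onsets.size), "em_density_per_min": None,
           "inter_em_interval_s": None, "p_em_after_click": None,
           "rem_min": rem_min}
    if rem_min > 0:
        out["em_density_per_min"] = onsets.size / rem_min

    gaps = []
    for a, b in hypnogram.rem_segments():
        t0, t1 = a * hypnogram.epoch_len_s, (b + 1) * hypnogram.epoch_len_s
        seg = onsets[(onsets >= t0) & (onsets < t1)]
        if seg.size >= 2:
            gaps.extend(np.diff(seg))
    if gaps:
        out["inter_em_interval_s"] = float(np.mean(gaps))

    if clicks.size:
        hits = sum(1 for t in clicks
                   if onsets.size and np.any((onsets > t) & (onsets <= t + window_s)))
        out["p_em_after_click"] = hits / clicks.size
    elif onsets.size == 0:
        out["p_em_after_click"] = 0.0
    if out["em_density_per_min"] is None and onsets.size == 0:
        out["em_density_per_min"] = 0.0 if rem_min > 0 else None
    return out
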
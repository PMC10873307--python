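"""Streaming simulator of the eye-movement-locked auditory stimulation.

The online protocol: the EOG is band-limited (0.3-5 Hz passband), and when
its absolute amplitude crosses a manually tuned threshold (50-100 µV) while
stimulation is enabled, a click is delivered 100 ms after the crossing;
detection then pauses for a refractory period (2 s by default). A deterministic
stage-based gate stands in for the experimenter, enabling stimulation after
a stable run of REM epochs and disabling it at any stage change or arousal.
In the control condition the identical protocol runs with the click muted.
"""
from __future__ import annotations

import numpy as np

from .types import Event, EventLog, Hypnogram, SignalRecord, StimulatorConfig


def make_click_waveform(fs: float = 44100.0, seed: int = 0,
                        duration_s: float = 0.050, ramp_s: float = 0.005
                        ) -> np.ndarray:
    """Stereo click stimulus: 50 ms of pink noise with 5 ms linear ramps.

    Returns an array of shape (2, n) with identical channels, peak-normalized.
    """
    if fs < 8000:
        raise ValueError("audio sampling rate must be at least 8 kHz")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs))
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    f[0] = f[1]
    spec *= f ** -0.5          # power spectral density ∝ 1/f
    spec[0] = 0.0
    mono = np.fft.irfft(spec, n)
    n_ramp = int(round(ramp_s * fs))
    env = np.ones(n)
    env[:n_ramp] = np.linspace(0.0, 1.0, n_ramp, endpoint=False)
    env[n - n_ramp:] = np.linspace(1.0, 0.0, n_ramp)
    mono = mono * env
    mono /= np.max(np.abs(mono))
    return np.vstack([mono, mono])


def gate_stimulation(hypnogram: Hypnogram, stable_epochs: int = 2) -> list[Event]:
    """Deterministic surrogate for the experimenter's on/off decisions.

    Emits ``stim_on`` at the start of the ``stable_epochs``-th consecutive
    R epoch and ``stim_off`` at the first subsequent stage change or at an
    arousal onset inside REM (whichever comes first). After an arousal the
    REM run count restarts.
    """
    events: list[Event] = []
    arousal_onsets = sorted(on for on, _ in hypnogram.arousals)
    run = 0
    on = False
    for i, stage in enumerate(hypnogram.stages):
        t0, t1 = hypnogram.epoch_bounds(i)
        if stage == "R":
            run += 1
        else:
            if on:
                events.append(Event(t_s=t0, type="stim_off", stage=stage))
                on = False
            run = 0
        if not on and run >= stable_epochs:
            events.append(Event(t_s=t0, type="stim_on", stage=stage))
            on = True
        if on:
            inside = [a for a in arousal_onsets if t0 <= a < t1]
            if inside:
                events.append(Event(t_s=inside[0], type="stim_off", stage=stage,
                                    meta={"reason": "arousal"}))
                on = False
                run = 0
    if on:
        events.append(Event(t_s=hypnogram.duration_s, type="stim_off",
                            stage=hypnogram.stages[-1]))
    return events


def _enabled_intervals(gate_events: list[Event], end_s: float
                       ) -> list[tuple[float, float]]:
    times = [(e.t_s, e.type) for e in gate_events if e.type in ("stim_on", "stim_off")]
    if any(b[0] < a[0] for a, b in zip(times, times[1:])):
        raise ValueError("gate events must be time-sorted")
    intervals, start = [], None
    for t, typ in times:
        if typ == "stim_on" and start is None:
            start = t
        elif typ == "stim_off" and start is not None:
            intervals.append((start, t))
            start = None
    if start is not None:
        intervals.append((start, end_s))
    return intervals


def run_em_detector(eog: SignalRecord, config: StimulatorConfig,
                    gate_events: list[Event],
                    hypnogram: Hypnogram | None = None) -> EventLog:
    """Threshold detector over a band-limited EOG stream.

    Processes samples strictly in time order. On the first sample with
    |amplitude| >= threshold inside an enabled interval and outside the
    refractory period, logs ``em_detected`` at the crossing time and
    ``click`` at crossing + click delay. Detection pauses ``refractory_s``
    after each stimulus. Muted mode logs identical events with the muted
    flag set.
    """
    if config.fs != eog.fs:
        raise ValueError("config fs must match the EOG sampling rate")
    intervals = _enabled_intervals(gate_events, eog.start_s + eog.duration_s)
    x = eog.samples
    fs = eog.fs
    events: list[Event] = [Event(e.t_s, e.type, e.stage, config.muted, dict(e.meta))
                           for e in gate_events]

    next_allowed = -np.inf
    for a, b in intervals:
        i = int(np.ceil((a - eog.start_s) * fs))
        stop = int(np.floor((b - eog.start_s) * fs))
        i = max(i, 0)
        stop = min(stop, x.size)
        while i < stop:
            t = eog.start_s + i / fs
            if t < next_allowed:
                # max() guarantees progress when t rounds just below the bound
                i = max(int(np.ceil((next_allowed - eog.start_s) * fs)), i + 1)
                continue
            if abs(x[i]) >= config.threshold_uv:
                click_t = t + config.click_delay_s
                stage = hypnogram.stage_at(t) if hypnogram else ""
                events.append(Event(t_s=t, type="em_detected", stage=stage,
                                    muted=config.muted,
                                    meta={"amplitude_uv": float(x[i])}))
                stage_c = (hypnogram.stage_at(click_t) if hypnogram
                           and click_t < hypnogram.duration_s else stage)
                events.append(Event(t_s=click_t, type="click", stage=stage_c,
                                    muted=config.muted))
                next_allowed = click_t + config.refractory_s
                i = max(int(np.ceil((next_allowed - eog.start_s) * fs)), i + 1)
                continue
            i += 1

    events.sort(key=lambda e: e.t_s)
    return EventLog(events=events)


def stimulation_accuracy(events: EventLog, hypnogram: Hypnogram,
                         true_em_times: np.ndarray,
                         window_s: float = 0.3) -> dict:
    """Post-hoc stimulation accuracy: % clicks in REM and % on the
    triggering eye movement.

    A click counts as 'on the EM' when it falls within ``window_s`` (the
    saccade's extent) after some ground-truth EM onset.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    clicks = events.click_times()
    n = clicks.size
    report = {"n_clicks": int(n), "n_in_rem": 0, "n_on_em": 0,
              "pct_in_rem": None, "pct_on_em": None, "empty": n == 0}
    if n == 0:
        return report
    in_rem = sum(1 for t in clicks
                 if t < hypnogram.duration_s and hypnogram.stage_at(t) == "R")
    em = np.asarray(true_em_times, dtype=float)
    on_em = 0
    for t in clicks:
        if em.size and np.any((em <= t) & (t <= em + window_s)):
            on_em += 1
    report.update(n_in_rem=int(in_rem), n_on_em=int(on_em),
                  pct_in_rem=100.0 * in_rem / n, pct_on_em=100.0 * on_em / n)
    return report
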
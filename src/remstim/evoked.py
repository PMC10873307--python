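"""Trial epoching, channel interpolation, ERP, and Morlet ERSP.

Trials span -2 to +3 s around each click. A candidate is excluded when the
click falls outside an R epoch, or when the trial window overlaps or comes
within 2 s of an annotated arousal/artifact, or when too many channels are
bad. Time-frequency power uses a 6-cycle complex Morlet wavelet on a
0.25-30 Hz grid; after transform, only -1 to +2.5 s is kept (edge-effect
trim) and each trial is baseline-corrected by the mean power over
-1 to 0 s per channel and frequency, expressed in dB:
``dB = 10 log10(power / baseline)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.polynomial import legendre as npleg
from scipy.signal import fftconvolve

from .montage import MONTAGE_21
from .types import Hypnogram, SignalRecord

TRIAL_WINDOW_S = (-2.0, 3.0)
ERSP_WINDOW_S = (-1.0, 2.5)
BASELINE_WINDOW_S = (-1.0, 0.0)
DEFAULT_FREQS_HZ = np.arange(0.25, 30.0 + 1e-9, 0.25)
ARTIFACT_GUARD_S = 2.0
BAD_CHANNEL_LIMIT = 0.25
N_CYCLES = 6.0

#: 6-cycle wavelets shorter than the trial require f >= ~1.2 Hz; estimates
#: below this are computed but flagged unreliable.
MIN_RELIABLE_FREQ_HZ = 1.2


@dataclass
class TrialSet:
    """Epoched trials (trials x channels x time, µV) plus exclusion bookkeeping."""

    data: np.ndarray
    time_axis: np.ndarray
    channels: list[str]
    fs: float
    condition: str = ""
    subject_id: str = ""
    click_times: np.ndarray = field(default_factory=lambda: np.array([]))
    excluded: list[dict] = field(default_factory=list)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass
class ERSPArray:
    """Single-trial baseline-corrected time-frequency power in dB."""

    values: np.ndarray  # trials x channels x freqs x times
    freqs: np.ndarray
    times: np.ndarray
    channels: list[str]
    baseline_window: tuple[float, float] = BASELINE_WINDOW_S
    unreliable_freqs: np.ndarray = field(default_factory=lambda: np.array([], bool))


def _near_interval(t0: float, t1: float, intervals, guard: float) -> bool:
    return any(t0 - guard < on + dur and t1 + guard > on for on, dur in intervals)


def epoch_trials(signals: list[SignalRecord], click_times_s, hypnogram: Hypnogram,
                 fs: float | None = None, condition: str = "",
                 subject_id: str = "") -> TrialSet:
    """Cut one candidate trial per click and apply the exclusion rules.

    Exclusion reasons (one primary reason per candidate, checked in order):
    ``non_rem``, ``near_artifact``, ``edge``.
    """
    fs = fs or signals[0].fs
    if any(s.fs != fs for s in signals):
        raise ValueError("all channels must share one sampling rate")
    n_pre = int(round(-TRIAL_WINDOW_S[0] * fs))
    n_post = int(round(TRIAL_WINDOW_S[1] * fs))
    time_axis = np.arange(-n_pre, n_post) / fs
    guards = list(hypnogram.arousals) + list(hypnogram.artifacts)
    n_samples = signals[0].n_samples

    kept, kept_times, excluded = [], [], []
    for t in np.asarray(click_times_s, dtype=float):
        t0, t1 = t + TRIAL_WINDOW_S[0], t + TRIAL_WINDOW_S[1]
        if not (0 <= t < hypnogram.duration_s) or hypnogram.stage_at(t) != "R":
            excluded.append({"t_s": t, "reason": "non_rem"})
            continue
        if _near_interval(t0, t1, guards, ARTIFACT_GUARD_S):
            excluded.append({"t_s": t, "reason": "near_artifact"})
            continue
        a = int(round(t * fs)) - n_pre
        b = a + n_pre + n_post
        if a < 0 or b > n_samples:
            excluded.append({"t_s": t, "reason": "edge"})
            continue
        kept.append(np.stack([s.samples[a:b] for s in signals]))
        kept_times.append(t)

    data = (np.stack(kept) if kept
            else np.zeros((0, len(signals), n_pre + n_post)))
    return TrialSet(data=data, time_axis=time_axis,
                    channels=[s.label for s in signals], fs=fs,
                    condition=condition, subject_id=subject_id,
                    click_times=np.array(kept_times), excluded=excluded)


def _spline_g(cosang: np.ndarray, m: int = 4, n_terms: int = 50) -> np.ndarray:
    """Perrin spherical-spline kernel g(cos angle) with Legendre truncation."""
    n = np.arange(1, n_terms + 1)
    coeffs = (2 * n + 1) / (n ** m * (n + 1) ** m)
    full = np.zeros(n_terms + 1)
    full[1:] = coeffs
    return npleg.legval(cosang, full) / (4 * np.pi)


def interpolation_matrix(good_pos: np.ndarray, bad_pos: np.ndarray,
                         m: int = 4, reg: float = 1e-5,
                         n_terms: int = 50) -> np.ndarray:
    """Spherical-spline operator mapping good-channel values to bad sites."""
    G = _spline_g(good_pos @ good_pos.T, m=m, n_terms=n_terms)
    G = G + reg * np.eye(G.shape[0])
    Gb = _spline_g(bad_pos @ good_pos.T, m=m, n_terms=n_terms)
    n_good = good_pos.shape[0]
    A = np.block([[G, np.ones((n_good, 1))], [np.ones((1, n_good)), np.zeros((1, 1))]])
    B = np.hstack([Gb, np.ones((bad_pos.shape[0], 1))])
    sol = np.linalg.solve(A, np.vstack([np.eye(n_good), np.zeros((1, n_good))]))
    return B @ sol


def interpolate_channels(trial: np.ndarray, channels: list[str],
                         bad_channels: list[str],
                         montage_positions: dict[str, np.ndarray]
                         ) -> np.ndarray | None:
    """Replace bad channels by spherical-spline estimates.

    Returns the corrected (channels x time) trial, or None when bad
    channels reach 25% of the montage (the trial is rejected instead).
    """
    unknown = set(bad_channels) - set(channels)
    if unknown:
        raise ValueError(f"unknown channels: {sorted(unknown)}")
    if not bad_channels:
        return trial.copy()
    if len(bad_channels) / len(channels) >= BAD_CHANNEL_LIMIT:
        return None
    bad_idx = [channels.index(c) for c in bad_channels]
    good_idx = [i for i in range(len(channels)) if i not in bad_idx]
    good_pos = np.stack([montage_positions[channels[i]] for i in good_idx])
    bad_pos = np.stack([montage_positions[channels[i]] for i in bad_idx])
    out = trial.copy()
    out[bad_idx] = interpolation_matrix(good_pos, bad_pos) @ trial[good_idx]
    return out


def compute_erp(trialset: TrialSet, subject_means: dict | None = None
                ) -> dict:
    """Trial-averaged ERP with a 95% CI.

    The CI uses the t quantile on per-subject means when ``subject_means``
    (subject -> channels x time array) is given, otherwise on trials.
    """
    from scipy import stats

    if trialset.n_trials < 2 and not subject_means:
        raise ValueError("need at least 2 trials")
    if subject_means:
        stack = np.stack(list(subject_means.values()))
    else:
        stack = trialset.data
    n = stack.shape[0]
    mean = stack.mean(axis=0)
    sem = stack.std(axis=0, ddof=1) / np.sqrt(n) if n > 1 else np.zeros_like(mean)
    tq = stats.t.ppf(0.975, n - 1) if n > 1 else 0.0
    return {"mean": mean, "ci_low": mean - tq * sem, "ci_high": mean + tq * sem,
            "grand_average": mean.mean(axis=0),
            "time_axis": trialset.time_axis, "n": n}


def morlet_wavelet(freq: float, fs: float, n_cycles: float = N_CYCLES) -> np.ndarray:
    """Unit-energy complex Morlet wavelet."""
    sigma_t = n_cycles / (2.0 * np.pi * freq)
    t = np.arange(-5 * sigma_t, 5 * sigma_t + 1.0 / fs, 1.0 / fs)
    w = np.exp(2j * np.pi * freq * t) * np.exp(-(t ** 2) / (2 * sigma_t ** 2))
    return w / np.sqrt(np.sum(np.abs(w) ** 2))


def compute_ersp(trialset: TrialSet, fs: float | None = None,
                 freqs_hz: np.ndarray | None = None, decim: int = 1) -> ERSPArray:
    """Single-trial Morlet ERSP with dB baseline correction.

    ``decim`` subsamples the output time axis (the transform itself runs at
    full rate). Baseline: per trial, channel and frequency, linear power is
    divided by its mean over -1 to 0 s before the dB transform, so the dB
    of the mean baseline power is 0 by construction.
    """
    fs = fs or trialset.fs
    freqs = DEFAULT_FREQS_HZ if freqs_hz is None else np.asarray(freqs_hz, float)
    if np.any(freqs >= fs / 2):
        raise ValueError("frequency grid exceeds Nyquist")
    keep = (trialset.time_axis >= ERSP_WINDOW_S[0] - 1e-9) & \
           (trialset.time_axis <= ERSP_WINDOW_S[1] + 1e-9)
    keep_idx = np.flatnonzero(keep)[::decim]
    times = trialset.time_axis[keep_idx]
    base = (times >= BASELINE_WINDOW_S[0]) & (times < BASELINE_WINDOW_S[1])

    n_tr, n_ch, n_t = trialset.data.shape
    flat = trialset.data.reshape(n_tr * n_ch, n_t)
    out = np.empty((n_tr, n_ch, freqs.size, keep_idx.size))
    for fi, f in enumerate(freqs):
        w = morlet_wavelet(f, fs)
        coef = fftconvolve(flat, w[None, :], mode="same", axes=1)
        power = np.abs(coef[:, keep_idx]) ** 2
        out[:, :, fi, :] = power.reshape(n_tr, n_ch, keep_idx.size)

    baseline = out[..., base].mean(axis=-1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        db = 10.0 * np.log10(out / baseline)
    return ERSPArray(values=db, freqs=freqs, times=times,
                     channels=list(trialset.channels),
                     unreliable_freqs=freqs < MIN_RELIABLE_FREQ_HZ)


def post_stimulus_change_db(ersp: ERSPArray, band_hz: tuple[float, float],
                            window_s: tuple[float, float]) -> float:
    """Mean dB change inside a time-frequency window, relative to the
    pre-stimulus level of the same band.

    Averaging dB across trials carries a negative offset (the log of a
    noisy power ratio); subtracting the band's mean dB over the baseline
    segment removes it, so a stationary signal gives ~0 and an injected
    band-power change surfaces at close to its injected dB value.
    """
    m = ersp.values.mean(axis=(0, 1))  # freq x time
    fsel = (ersp.freqs >= band_hz[0]) & (ersp.freqs <= band_hz[1])
    tsel = (ersp.times >= window_s[0]) & (ersp.times <= window_s[1])
    bsel = (ersp.times >= ersp.baseline_window[0]) & \
           (ersp.times < ersp.baseline_window[1])
    return float(m[np.ix_(fsel, tsel)].mean() - m[np.ix_(fsel, bsel)].mean())
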
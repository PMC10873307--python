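"""Synthetic EOG, EEG and EMG with known injected structure.

EOG carries biphasic saccadic deflections (50-100 µV by default) at Poisson
times restricted to REM epochs over a low-amplitude pink-noise background.
EEG is 1/f-coloured noise per channel, with REM-locked theta content, plus
per-click injections: an additive ERP (delayed P2 and a sustained
negativity) and multiplicative band-limited power modulations (beta
increase, theta decrease) whose dB magnitude the ERSP baseline transform
recovers directly. EMG shows atonia (reduced amplitude) in REM.
"""
from __future__ import annotations

import numpy as np
from scipy import signal as sps

from ..types import Hypnogram, SignalRecord, SyntheticGroundTruth


def pink_noise(n: int, rms: float, rng: np.random.Generator,
               exponent: float = 1.0) -> np.ndarray:
    """1/f^exponent coloured Gaussian noise with the requested RMS."""
    if n == 0:
        return np.zeros(0)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    spec *= f ** (-exponent / 2.0)
    spec[0] = 0.0
    x = np.fft.irfft(spec, n)
    std = x.std()
    return x * (rms / std) if std > 0 else x


def _saccade_template(width_s: float, fs: float) -> np.ndarray:
    """Biphasic raised-cosine pulse: positive lobe then negative lobe."""
    n = max(int(round(width_s * fs)), 4)
    half = n // 2
    lobe = 0.5 * (1 - np.cos(2 * np.pi * np.arange(half) / half))
    return np.concatenate([lobe, -lobe])


def _stage_mask(hypnogram: Hypnogram, stage: str, n: int, fs: float) -> np.ndarray:
    mask = np.zeros(n, dtype=bool)
    for i, s in enumerate(hypnogram.stages):
        if s == stage:
            a = int(round(i * hypnogram.epoch_len_s * fs))
            b = int(round((i + 1) * hypnogram.epoch_len_s * fs))
            mask[a:min(b, n)] = True
    return mask


def generate_rem_eog(hypnogram: Hypnogram, saccade_rate_per_min: float = 6.0,
                     amp_range_uv: tuple[float, float] = (50.0, 100.0),
                     fs: float = 500.0, seed: int = 0,
                     noise_rms_uv: float = 5.0,
                     saccade_width_s: float = 0.3,
                     ) -> tuple[SignalRecord, np.ndarray]:
    """EOG channel with REM-restricted saccades; returns exact onset times.

    Saccade onsets follow a homogeneous Poisson process of the given rate
    over REM epochs only; each saccade is a biphasic raised-cosine pulse
    with peak amplitude drawn uniformly from ``amp_range_uv`` and random
    polarity. Background noise RMS stays far below the lower amplitude
    bound so threshold detection is well posed.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    lo, hi = amp_range_uv
    if not (0 < lo <= hi <= 500):
        raise ValueError("amplitude range must lie within (0, 500] µV")
    if saccade_rate_per_min < 0:
        raise ValueError("saccade rate must be non-negative")

    rng = np.random.default_rng(seed)
    n = int(round(hypnogram.duration_s * fs))
    x = pink_noise(n, noise_rms_uv, rng)
    template = _saccade_template(saccade_width_s, fs)

    em_times: list[float] = []
    rate_per_s = saccade_rate_per_min / 60.0
    if rate_per_s > 0:
        for i, stage in enumerate(hypnogram.stages):
            if stage != "R":
                continue
            t0, t1 = hypnogram.epoch_bounds(i)
            t1 = min(t1, hypnogram.duration_s - saccade_width_s)
            if t1 <= t0:
                continue
            k = rng.poisson(rate_per_s * (t1 - t0))
            onsets = np.sort(rng.uniform(t0, t1, size=k))
            for t in onsets:
                amp = rng.uniform(lo, hi) * rng.choice([-1.0, 1.0])
                a = int(round(t * fs))
                b = min(a + template.size, n)
                x[a:b] += amp * template[: b - a]
                em_times.append(float(t))

    record = SignalRecord(label="EOG-L", kind="EOG", fs=fs, samples=x)
    return record, np.array(em_times)


def _band_gain_envelope(n: int, fs: float, click_times: np.ndarray,
                        window_s: tuple[float, float], gain_db: float) -> np.ndarray:
    """Amplitude-gain envelope implementing a post-click band-power change.

    Inside each click's window the gain is 10^(dB/20) with 100-ms raised-
    cosine flanks; elsewhere 1.
    """
    g = 10.0 ** (gain_db / 20.0)
    env = np.zeros(n)
    ramp_s = 0.1
    w0, w1 = window_s
    for t in click_times:
        a, b = t + w0, t + w1
        ta = np.arange(max(int((a - ramp_s) * fs), 0), min(int((b + ramp_s) * fs), n))
        if ta.size == 0:
            continue
        ts = ta / fs
        w = np.ones_like(ts, dtype=float)
        rise = ts < a
        fall = ts > b
        w[rise] = 0.5 * (1 + np.cos(np.pi * (a - ts[rise]) / ramp_s))
        w[fall] = 0.5 * (1 + np.cos(np.pi * (ts[fall] - b) / ramp_s))
        env[ta] = np.maximum(env[ta], w)
    return 1.0 + (g - 1.0) * env


def _bandpass(x: np.ndarray, band: tuple[float, float], fs: float) -> np.ndarray:
    sos = sps.butter(4, band, btype="bandpass", output="sos", fs=fs)
    return sps.sosfiltfilt(sos, x)


def _erp_template(n_post: int, fs: float, gt: SyntheticGroundTruth) -> np.ndarray:
    t = np.arange(n_post) / fs
    erp = gt.p2_amplitude_uv * np.exp(-0.5 * ((t - gt.p2_latency_s) / 0.045) ** 2)
    w0, w1 = gt.negativity_window_s
    env = np.zeros_like(t)
    inside = (t >= w0) & (t <= w1)
    env[inside] = np.sin(np.pi * (t[inside] - w0) / (w1 - w0)) ** 2
    return erp + gt.negativity_amplitude_uv * env


def generate_eeg_with_responses(hypnogram: Hypnogram, click_times_s,
                                ground_truth: SyntheticGroundTruth,
                                montage: tuple[str, ...] | list[str],
                                fs: float = 500.0, seed: int = 0,
                                background_rms_uv: float = 30.0,
                                rem_theta_rms_uv: float = 6.0,
                                ) -> list[SignalRecord]:
    """EEG channels with click-locked injected responses.

    Each channel is independent 1/f background (REM epochs additionally
    carry theta-band noise). Per click, the ERP template is added and the
    beta/theta band-limited content is scaled by the ground-truth dB gains
    inside their windows: ``x <- x + (g(t) - 1) * bandpass(x)``, which
    multiplies band power by ``g(t)^2`` and so surfaces in the ERSP as the
    injected dB value. Zero-amplitude ground truth returns pure background.
    """
    click_times = np.asarray(click_times_s, dtype=float)
    n = int(round(hypnogram.duration_s * fs))
    if click_times.size and (click_times.min() < 0 or click_times.max() >= hypnogram.duration_s):
        raise ValueError("click time outside the record")

    rng = np.random.default_rng(seed)
    rem_mask = _stage_mask(hypnogram, "R", n, fs)
    erp = _erp_template(int(round(2.0 * fs)), fs, ground_truth)

    records = []
    for label in montage:
        x = pink_noise(n, background_rms_uv, rng)
        if rem_theta_rms_uv > 0 and rem_mask.any():
            theta = pink_noise(n, rem_theta_rms_uv, rng, exponent=0.0)
            theta = _bandpass(theta, ground_truth.theta_band_hz, fs)
            theta *= rem_theta_rms_uv / max(theta.std(), 1e-12)
            x = x + theta * rem_mask

        if click_times.size:
            if ground_truth.p2_amplitude_uv or ground_truth.negativity_amplitude_uv:
                chan_gain = rng.normal(1.0, 0.1)
                for t in click_times:
                    a = int(round(t * fs))
                    b = min(a + erp.size, n)
                    x[a:b] += chan_gain * erp[: b - a]
            for band, window, db in (
                (ground_truth.beta_band_hz, ground_truth.beta_window_s,
                 ground_truth.beta_amplitude_db),
                (ground_truth.theta_band_hz, ground_truth.theta_window_s,
                 ground_truth.theta_amplitude_db),
            ):
                if db == 0:
                    continue
                env = _band_gain_envelope(n, fs, click_times, window, db)
                x = x + (env - 1.0) * _bandpass(x, band, fs)

        records.append(SignalRecord(label=label, kind="EEG", fs=fs, samples=x))
    return records


def generate_emg(hypnogram: Hypnogram, fs: float = 500.0, seed: int = 0,
                 wake_rms_uv: float = 20.0, atonia_rms_uv: float = 3.0) -> SignalRecord:
    """Chin EMG: broadband noise with REM atonia (strongly reduced amplitude)."""
    rng = np.random.default_rng(seed)
    n = int(round(hypnogram.duration_s * fs))
    x = pink_noise(n, 1.0, rng, exponent=0.0)
    scale = np.full(n, wake_rms_uv)
    scale[_stage_mask(hypnogram, "R", n, fs)] = atonia_rms_uv
    for stage, s in (("N2", 8.0), ("N3", 6.0), ("N1", 12.0)):
        scale[_stage_mask(hypnogram, stage, n, fs)] = s
    return SignalRecord(label="EMG", kind="EMG", fs=fs, samples=x * scale)
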
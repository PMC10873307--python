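"""Chebyshev type II band-pass filters used by the online detector and the
offline pre-processing.

Four named designs are registered, each specified by its 3-dB passband
edges, stopband edges, and minimum stopband attenuation:

=============  ===============  ===============  ============
name           passband (Hz)    stopband (Hz)    atten. (dB)
=============  ===============  ===============  ============
online_eog     0.3 – 5          <0.1, >15        50
offline_eeg    0.16 – 35.8      <0.05, >45       100
offline_eog    0.36 – 8.2       <0.26, >10       100
offline_emg    9.56 – 100.35    <8.97, >105      100
=============  ===============  ===============  ============

Designs are minimum-order Chebyshev II realized in second-order sections;
high orders with sub-Hz edges at 500 Hz are numerically unstable in
transfer-function form. The printed figures are treated as single-pass
targets; zero-phase (forward-backward) application doubles the attenuation
in dB.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .types import SignalRecord


@dataclass(frozen=True)
class FilterSpec:
    name: str
    passband_3db_hz: tuple[float, float]
    stopband_hz: tuple[float, float]
    stopband_atten_db: float
    mode: str = "zero_phase"  # causal | zero_phase

    def __post_init__(self) -> None:
        s1, s2 = self.stopband_hz
        f1, f2 = self.passband_3db_hz
        if not (s1 < f1 < f2 < s2):
            raise ValueError("band edges must satisfy s1 < f1 < f2 < s2")
        if self.stopband_atten_db <= 0:
            raise ValueError("attenuation must be positive")
        if self.mode not in ("causal", "zero_phase"):
            raise ValueError(f"unknown mode {self.mode!r}")


#: The four designs named in the pre-processing pipeline.
SPEC_REGISTRY: dict[str, FilterSpec] = {
    "online_eog": FilterSpec("online_eog", (0.3, 5.0), (0.1, 15.0), 50.0, mode="causal"),
    "offline_eeg": FilterSpec("offline_eeg", (0.16, 35.8), (0.05, 45.0), 100.0),
    "offline_eog": FilterSpec("offline_eog", (0.36, 8.2), (0.26, 10.0), 100.0),
    "offline_emg": FilterSpec("offline_emg", (9.56, 100.35), (8.97, 105.0), 100.0),
}


@dataclass
class FilterDesign:
    spec: FilterSpec
    order: int
    sos: np.ndarray
    fs: float


def get_spec(name: str, mode: str | None = None) -> FilterSpec:
    """Look up a named filter spec, optionally overriding its mode."""
    spec = SPEC_REGISTRY[name]
    if mode is not None and mode != spec.mode:
        spec = FilterSpec(spec.name, spec.passband_3db_hz, spec.stopband_hz,
                          spec.stopband_atten_db, mode=mode)
    return spec


def design_cheby2_bandpass(spec: FilterSpec, fs: float) -> FilterDesign:
    """Minimum-order Chebyshev II band-pass meeting ``spec`` at rate ``fs``.

    Passband ripple is held to <= 3 dB inside the passband edges and the
    equiripple stopband attains at least the specified attenuation at and
    beyond the stopband edges (single pass).
    """
    if spec.stopband_hz[1] >= fs / 2:
        raise ValueError(
            f"stopband edge {spec.stopband_hz[1]} Hz not below Nyquist ({fs / 2} Hz)")
    order, wn = signal.cheb2ord(spec.passband_3db_hz, spec.stopband_hz,
                                gpass=3.0, gstop=spec.stopband_atten_db, fs=fs)
    sos = signal.cheby2(order, spec.stopband_atten_db, wn, btype="bandpass",
                        output="sos", fs=fs)
    design = FilterDesign(spec=spec, order=order, sos=sos, fs=fs)
    if not is_stable(design):
        raise ValueError(f"design for {spec.name} at fs={fs} is unstable")
    return design


def is_stable(design: FilterDesign) -> bool:
    _, poles, _ = signal.sos2zpk(design.sos)
    return bool(np.all(np.abs(poles) < 1.0))


def magnitude_response(design: FilterDesign, freqs_hz) -> np.ndarray:
    """Single-pass attenuation in dB (positive = attenuated) at ``freqs_hz``."""
    freqs = np.atleast_1d(np.asarray(freqs_hz, dtype=float))
    if np.any(freqs >= design.fs / 2):
        raise ValueError("frequencies must be below Nyquist")
    _, h = signal.sosfreqz(design.sos, worN=freqs, fs=design.fs)
    mag = np.abs(h)
    with np.errstate(divide="ignore"):
        return -20.0 * np.log10(mag)


def apply_filter(design: FilterDesign, record: SignalRecord) -> SignalRecord:
    """Filter a signal per the design's mode.

    Causal mode runs a single forward pass (online detector semantics:
    the output at t depends only on samples up to t). Zero-phase mode runs
    forward-backward with reflected edge padding, squaring the magnitude
    response.
    """
    if record.fs != design.fs:
        raise ValueError(f"signal fs {record.fs} != design fs {design.fs}")
    if design.spec.mode == "causal":
        out = signal.sosfilt(design.sos, record.samples)
    else:
        padlen = min(record.n_samples - 1, 3 * (design.order + 1) * 2)
        out = signal.sosfiltfilt(design.sos, record.samples, padtype="even",
                                 padlen=padlen)
    return SignalRecord(label=record.label, kind=record.kind, fs=record.fs,
                        samples=out, start_s=record.start_s)


def design_named(name: str, fs: float, mode: str | None = None) -> FilterDesign:
    """Convenience: design a registered spec by name."""
    return design_cheby2_bandpass(get_spec(name, mode=mode), fs)
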
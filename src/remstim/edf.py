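"""Minimal EDF (European Data Format) writer for polysomnography fixtures.

EDF stores each signal as 16-bit integers with a per-signal linear
physical/digital calibration, in fixed-duration data records. This writer
covers exactly what the synthetic fixtures need: equal-rate continuous
channels, one-second records, physical units in µV. Files written here are
read back with any standard EDF reader (the tests use MNE's).
"""
from __future__ import annotations

import datetime as _dt
import math
from pathlib import Path

import numpy as np

from .types import SignalRecord

_DIG_MIN, _DIG_MAX = -32768, 32767


def _ascii(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII bytes")
    return s.ljust(width).encode("ascii")


def write_edf(path: str | Path, records: list[SignalRecord],
              record_duration_s: float = 1.0,
              start: _dt.datetime | None = None) -> Path:
    """Write channels to an EDF file.

    All channels must share one sampling rate. Signals are zero-padded to a
    whole number of data records. Physical min/max are set symmetrically per
    channel from the data so 16-bit quantization error is (max |x|)/32767.
    """
    path = Path(path)
    if not records:
        raise ValueError("no signals to write")
    fs = records[0].fs
    if any(r.fs != fs for r in records):
        raise ValueError("all channels must share one sampling rate")
    spr = fs * record_duration_s
    if abs(spr - round(spr)) > 1e-9:
        raise ValueError("record duration must hold an integer number of samples")
    spr = int(round(spr))
    n_samp = max(r.n_samples for r in records)
    n_records = math.ceil(n_samp / spr)
    start = start or _dt.datetime(2000, 1, 1, 23, 30, 0)

    phys = []
    digital = np.zeros((len(records), n_records * spr), dtype="<i2")
    for i, r in enumerate(records):
        pmax = float(np.max(np.abs(r.samples))) if r.n_samples else 1.0
        pmax = max(pmax, 1e-6)
        phys.append(pmax)
        x = np.zeros(n_records * spr)
        x[: r.n_samples] = r.samples
        # same affine map readers apply: [-pmax, pmax] <-> [dig_min, dig_max]
        scale = 2.0 * pmax / (_DIG_MAX - _DIG_MIN)
        digital[i] = np.clip(np.round((x + pmax) / scale) + _DIG_MIN,
                             _DIG_MIN, _DIG_MAX).astype("<i2")

    ns = len(records)
    header = b"".join([
        _ascii(0, 8),                                   # version
        _ascii("X X X X", 80),                           # patient id (anonymous)
        _ascii("Startdate X X X X", 80),                 # recording id
        _ascii(start.strftime("%d.%m.%y"), 8),
        _ascii(start.strftime("%H.%M.%S"), 8),
        _ascii(256 * (ns + 1), 8),                       # header bytes
        _ascii("", 44),                                  # reserved
        _ascii(n_records, 8),
        _ascii(f"{record_duration_s:g}", 8),
        _ascii(ns, 4),
    ])
    fields = [
        [_ascii(r.label, 16) for r in records],
        [_ascii(f"{r.kind} channel", 80) for r in records],
        [_ascii("uV", 8) for _ in records],
        [_ascii(f"{-p:.6g}"[:8], 8) for p in phys],      # physical min
        [_ascii(f"{p:.6g}"[:8], 8) for p in phys],       # physical max
        [_ascii(_DIG_MIN, 8) for _ in records],
        [_ascii(_DIG_MAX, 8) for _ in records],
        [_ascii("", 80) for _ in records],               # prefiltering
        [_ascii(spr, 8) for _ in records],
        [_ascii("", 32) for _ in records],               # reserved
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for block in fields:
            fh.writelines(block)
        # data records: channel-major within each record
        for rec in range(n_records):
            sl = slice(rec * spr, (rec + 1) * spr)
            for i in range(ns):
                fh.write(digital[i, sl].tobytes())
    return path
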
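"""ERP and ERSP of the simulated night's click-locked trials.

Filters the EEG with the offline band-pass, epochs trials around each
click with the exclusion rules, and writes the grand-average ERP and the
trial-mean time-frequency (dB) map under results/evoked/, together with a
summary figure.
"""
from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from remstim.cli import _read_edf, _read_hypnogram
from remstim.evoked import compute_erp, compute_ersp, epoch_trials
from remstim.filters import apply_filter, design_named

ROOT = Path(__file__).resolve().parents[1] / "results"
NIGHT, OUT = ROOT / "night", ROOT / "evoked"
OUT.mkdir(parents=True, exist_ok=True)

hyp = _read_hypnogram(NIGHT / "hypnogram.tsv", NIGHT / "annotations.tsv")
events = pd.read_csv(NIGHT / "events.tsv", sep="\t")
clicks = events.loc[events["type"] == "click", "t_s"].to_numpy(float)

eeg = [r for r in _read_edf(NIGHT / "signals.edf") if r.kind == "EEG"]
design = design_named("offline_eeg", eeg[0].fs)
eeg = [apply_filter(design, r) for r in eeg]

trials = epoch_trials(eeg, clicks, hyp)
print(f"{trials.n_trials} trials kept of {clicks.size} clicks "
      f"({len(trials.excluded)} excluded: "
      f"{ {e['reason'] for e in trials.excluded} or 'none'})")

erp = compute_erp(trials)
pd.DataFrame({"time_s": erp["time_axis"], "erp_uv": erp["grand_average"]}
             ).to_csv(OUT / "erp.tsv", sep="\t", index=False)

freqs = np.arange(2.0, 30.0 + 1e-9, 0.5)
ersp = compute_ersp(trials, freqs_hz=freqs, decim=5)
mean_map = ersp.values.mean(axis=(0, 1))
pd.DataFrame(mean_map, index=ersp.freqs, columns=np.round(ersp.times, 3)
             ).to_csv(OUT / "ersp_mean_db.tsv", sep="\t")

fig, axes = plt.subplots(2, 1, figsize=(8, 7), sharex=False)
axes[0].plot(erp["time_axis"], erp["grand_average"], "k")
axes[0].axvline(0, color="r", ls="--", lw=0.8)
axes[0].set(xlabel="time from click (s)", ylabel="ERP (µV)",
            title="grand-average click-locked ERP")
im = axes[1].pcolormesh(ersp.times, ersp.freqs,
                        mean_map - mean_map[:, ersp.times < 0].mean(
                            axis=1, keepdims=True),
                        cmap="RdBu_r", vmin=-1.5, vmax=1.5)
axes[1].set(xlabel="time from click (s)", ylabel="frequency (Hz)",
            title="trial-mean ERSP change from baseline (dB)")
fig.colorbar(im, ax=axes[1], label="dB")
fig.tight_layout()
fig.savefig(OUT / "evoked_summary.png", dpi=110)

t, ga = erp["time_axis"], erp["grand_average"]
sel = (t > 0.05) & (t < 0.5)
print(f"P2 peak at {t[sel][np.argmax(ga[sel])]*1000:.0f} ms; "
      f"tables and figure in {OUT}")
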
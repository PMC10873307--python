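"""Simulate one stimulation night and write the fixture dataset.

Generates a 30-minute synthetic polysomnography record (hypnogram with the
control-night stage composition, EOG with REM saccades, eight EEG channels
with click-locked responses, chin EMG with REM atonia), runs the online
eye-movement detector over it, and writes EDF + TSV fixtures plus the
ground-truth eye-movement times under results/night/.
"""
import sys
from pathlib import Path

import numpy as np

from remstim import closed_loop
from remstim.filters import apply_filter, design_named
from remstim.montage import MONTAGE_21
from remstim.synth import (TABLE1_CNT_FRACTIONS, generate_behavioural_dataset,
                           generate_eeg_with_responses, generate_emg,
                           generate_hypnogram, generate_rem_eog,
                           write_fixture_dataset)
from remstim.types import StimulatorConfig, SyntheticGroundTruth

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path(__file__).resolve().parents[1] / "results" / "night"
FS = 250.0
DURATION_MIN = 30.0

hyp = generate_hypnogram(DURATION_MIN, TABLE1_CNT_FRACTIONS, seed=SEED)
eog, em_times = generate_rem_eog(hyp, fs=FS, seed=SEED + 1)
gt = SyntheticGroundTruth(em_times_s=em_times, seed=SEED)

gate = closed_loop.gate_stimulation(hyp)
filtered = apply_filter(design_named("online_eog", FS), eog)
log = closed_loop.run_em_detector(
    filtered, StimulatorConfig(threshold_uv=50.0, fs=FS), gate, hypnogram=hyp)

eeg = generate_eeg_with_responses(hyp, log.click_times(), gt, MONTAGE_21[:8],
                                  fs=FS, seed=SEED + 2)
emg = generate_emg(hyp, fs=FS, seed=SEED + 3)
sessions = generate_behavioural_dataset(n_subjects=19, seed=SEED + 4)

manifest = write_fixture_dataset(eeg + [eog, emg], hyp, log, sessions, OUT,
                                 seed=SEED)
np.savetxt(OUT / "em_times.tsv", em_times, header="em_time_s", comments="",
           fmt="%.6f")

rem_pct = 100 * hyp.stages.count("R") / hyp.n_epochs
print(f"night written to {OUT}")
print(f"  {hyp.n_epochs} epochs, {rem_pct:.1f}% REM, "
      f"{em_times.size} ground-truth eye movements, "
      f"{log.click_times().size} clicks")
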
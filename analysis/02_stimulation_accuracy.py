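"""Score the closed-loop stimulation of the simulated night.

Reads results/night/, recomputes offline eye-movement detections, the
Table-1-style sleep summary, and the stimulation-accuracy percentages
(% clicks inside REM, % clicks on the triggering saccade), and writes
results/stimulation/.
"""
import json
from pathlib import Path

import numpy as np
import pandas as pd

from remstim import closed_loop, rem_metrics
from remstim.cli import _read_edf, _read_hypnogram
from remstim.types import Event, EventLog

ROOT = Path(__file__).resolve().parents[1] / "results"
NIGHT, OUT = ROOT / "night", ROOT / "stimulation"
OUT.mkdir(parents=True, exist_ok=True)

hyp = _read_hypnogram(NIGHT / "hypnogram.tsv", NIGHT / "annotations.tsv")
events = pd.read_csv(NIGHT / "events.tsv", sep="\t")
clicks = events.loc[events["type"] == "click", "t_s"].to_numpy(float)
true_em = np.atleast_1d(np.loadtxt(NIGHT / "em_times.tsv", skiprows=1))

eog = next(r for r in _read_edf(NIGHT / "signals.edf") if r.kind == "EOG")
ems = rem_metrics.detect_em_offline(eog, hyp, threshold_uv=50.0)
summary = rem_metrics.sleep_summary(hyp, em_events=ems)
stats_em = rem_metrics.em_statistics(ems, clicks, hyp)

log = EventLog(events=[Event(t_s=float(t), type="click") for t in clicks])
acc = closed_loop.stimulation_accuracy(log, hyp, true_em)

pd.DataFrame([
    ("Recording (min)", summary.recording_min),
    ("TST (min)", summary.tst_min),
    ("Efficiency (%)", summary.efficiency_pct),
    ("REM (%)", summary.stage_pct.get("REM")),
    ("Phasic REM (%)", summary.phasic_pct),
    ("Tonic REM (%)", summary.tonic_pct),
    ("EM density (EM/min)", summary.em_density_per_min),
    ("Number of REM segments", summary.n_rem_segments),
], columns=["variable", "value"]).to_csv(OUT / "sleep_summary.tsv", sep="\t",
                                         index=False)
(OUT / "accuracy.json").write_text(json.dumps(
    {**acc, "p_em_after_click": stats_em["p_em_after_click"],
     "em_density_per_min": stats_em["em_density_per_min"]}, indent=2))

print(f"{acc['n_clicks']} clicks: {acc['pct_in_rem']:.1f}% in REM, "
      f"{acc['pct_on_em']:.1f}% on the triggering eye movement")
print(f"EM density {stats_em['em_density_per_min']:.2f}/min; "
      f"P(EM within 2.5 s after click) = {stats_em['p_em_after_click']:.2f}")
print(f"tables in {OUT}")
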
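"""Write a synthetic night to disk: EDF signals + TSV tables + manifest."""
from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from ..edf import write_edf
from ..types import EventLog, Hypnogram, SignalRecord, BehaviouralSession
from .behaviour import sessions_to_frame


def hypnogram_frame(hypnogram: Hypnogram) -> pd.DataFrame:
    return pd.DataFrame({"epoch_index": range(hypnogram.n_epochs),
                         "stage": hypnogram.stages})


def annotations_frame(hypnogram: Hypnogram) -> pd.DataFrame:
    rows = [("arousal", on, dur) for on, dur in hypnogram.arousals]
    rows += [("artifact", on, dur) for on, dur in hypnogram.artifacts]
    rows.sort(key=lambda r: r[1])
    return pd.DataFrame(rows, columns=["kind", "onset_s", "duration_s"])


def events_frame(events: EventLog) -> pd.DataFrame:
    return pd.DataFrame(
        [(e.t_s, e.type, e.stage, e.muted, json.dumps(e.meta, sort_keys=True))
         for e in events.events],
        columns=["t_s", "type", "stage", "muted", "meta"])


def write_fixture_dataset(records: list[SignalRecord], hypnogram: Hypnogram,
                          events: EventLog | None,
                          sessions: list[BehaviouralSession] | None,
                          out_dir: str | Path, seed: int = 0) -> dict:
    """Persist one synthetic night; returns the manifest (also written as JSON).

    Layout: ``signals.edf``, ``hypnogram.tsv`` (epoch_index, stage),
    ``annotations.tsv``, ``events.tsv``, ``behaviour.tsv``, ``manifest.json``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for r in records:
        if abs(r.duration_s - hypnogram.duration_s) > 1.0 / r.fs + 1e-9:
            raise ValueError(f"channel {r.label} duration inconsistent with hypnogram")

    manifest: dict = {"seed": seed, "files": {}}
    edf_path = out / "signals.edf"
    write_edf(edf_path, records)
    manifest["files"]["signals"] = edf_path.name

    tables = {
        "hypnogram": hypnogram_frame(hypnogram),
        "annotations": annotations_frame(hypnogram),
    }
    if events is not None:
        tables["events"] = events_frame(events)
    if sessions is not None:
        tables["behaviour"] = sessions_to_frame(sessions)
    for name, df in tables.items():
        p = out / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        manifest["files"][name] = p.name

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
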
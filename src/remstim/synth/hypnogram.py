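"""Synthetic hypnograms with requested stage composition.

Epochs are allocated to stages by quota (largest-remainder rounding of the
requested fractions), split into bouts of geometrically distributed length,
and the bouts are shuffled. Empirical stage fractions therefore match the
request up to rounding for any night length, while the bout structure gives
the contiguous REM segments the closed-loop gating needs.
"""
from __future__ import annotations

import numpy as np

from ..types import EPOCH_LEN_S, STAGES, Hypnogram

#: Whole-night stage composition emulating the control-night means
#: (stage percentages of total sleep time, with the small wake remainder
#: folded in so the fractions cover the full record).
TABLE1_CNT_FRACTIONS: dict[str, float] = {
    "W": 0.0311, "N1": 0.1002, "N2": 0.3982, "N3": 0.2626, "R": 0.2079,
}


def generate_hypnogram(duration_min: float, stage_fractions: dict[str, float],
                       mean_bout_len_s: float = 90.0, seed: int = 0,
                       arousal_rate_per_h: float = 0.0) -> Hypnogram:
    """Generate a stage sequence whose composition matches ``stage_fractions``.

    Parameters
    ----------
    duration_min : total record length; must be a whole number of 30-s epochs.
    stage_fractions : mapping stage -> fraction of epochs; must sum to 1.
    mean_bout_len_s : mean length of a contiguous same-stage bout.
    seed : RNG seed; identical seeds give identical hypnograms.
    arousal_rate_per_h : optional Poisson rate of 5-s arousal annotations.
    """
    total = sum(stage_fractions.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"stage fractions must sum to 1 (got {total})")
    bad = set(stage_fractions) - set(STAGES)
    if bad:
        raise ValueError(f"unknown stages {sorted(bad)}")
    n_epochs = duration_min * 60.0 / EPOCH_LEN_S
    if abs(n_epochs - round(n_epochs)) > 1e-9:
        raise ValueError("duration must be a whole number of 30-s epochs")
    n_epochs = int(round(n_epochs))

    rng = np.random.default_rng(seed)

    # largest-remainder quota per stage
    stages_order = [s for s in STAGES if stage_fractions.get(s, 0) > 0]
    exact = {s: stage_fractions[s] * n_epochs for s in stages_order}
    counts = {s: int(np.floor(v)) for s, v in exact.items()}
    short = n_epochs - sum(counts.values())
    for s in sorted(stages_order, key=lambda s: exact[s] - counts[s], reverse=True)[:short]:
        counts[s] += 1

    mean_bout_epochs = max(mean_bout_len_s / EPOCH_LEN_S, 1.0)
    bouts: list[tuple[str, int]] = []
    for s in stages_order:
        remaining = counts[s]
        while remaining > 0:
            size = min(int(rng.geometric(1.0 / mean_bout_epochs)), remaining)
            bouts.append((s, int(size)))
            remaining -= size
    rng.shuffle(bouts)

    stages: list[str] = []
    for s, size in bouts:
        stages.extend([s] * size)

    arousals: list[tuple[float, float]] = []
    if arousal_rate_per_h > 0:
        n_ar = rng.poisson(arousal_rate_per_h * duration_min / 60.0)
        onsets = np.sort(rng.uniform(0, n_epochs * EPOCH_LEN_S - 5.0, size=n_ar))
        arousals = [(float(t), 5.0) for t in onsets]

    return Hypnogram(stages=stages, arousals=arousals)
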
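"""The 21-site 10-20 scalp montage used for EEG recording.

Positions come from the standard 10-20 template (via MNE) projected onto
the unit sphere, which is what the spherical-spline interpolation expects.
"""
from __future__ import annotations

from functools import lru_cache

import numpy as np

#: The 21 scalp sites, referenced to Cpz at acquisition.
MONTAGE_21 = (
    "Fpz", "Fp1", "Fp2", "Fz", "F3", "F4", "F7", "F8",
    "Cz", "C3", "C4", "Pz", "P3", "P4", "P7", "P8",
    "Oz", "O1", "O2", "T7", "T8",
)


@lru_cache(maxsize=1)
def unit_sphere_positions() -> dict[str, np.ndarray]:
    """3-D unit-sphere coordinates for every site in :data:`MONTAGE_21`.

    Head-frame positions are re-centred on the sphere best fitting the
    scalp sites before normalization.
    """
    import mne

    montage = mne.channels.make_standard_montage("standard_1020")
    pos = montage.get_positions()["ch_pos"]
    pts = np.array([pos[ch] for ch in MONTAGE_21])
    centre = pts.mean(axis=0)
    centred = pts - centre
    unit = centred / np.linalg.norm(centred, axis=1, keepdims=True)
    return {ch: unit[i] for i, ch in enumerate(MONTAGE_21)}
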
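"""Nonparametric suprathreshold cluster test for paired condition
differences on ERP (1-D) and ERSP (2-D) maps.

Pixels where a two-tailed Welch t-test between conditions gives p < 0.05
are grouped into connected components (4-connectivity in freq x time,
2-neighbour in 1-D), separately for positive and negative t. The observed
cluster sizes (in pixels) are scored against the permutation distribution
of the maximal suprathreshold cluster size obtained by swapping the two
condition labels within subjects; permutations are sampled without
repetition, falling back to exhaustive enumeration when 2^n <= n_perm.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, stats

DEFAULT_N_PERM = 1600
CLUSTER_ALPHA = 0.05


@dataclass
class ClusterResult:
    mask: np.ndarray
    size_px: int
    sign: str  # positive | negative
    p_value: float | None = None
    null_sizes: np.ndarray = field(default_factory=lambda: np.array([]))


def welch_t_map(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pixelwise unequal-variance t-test between two groups of subject maps.

    ``a`` and ``b`` are subjects x map (any map shape). Pixels with zero
    variance in both groups get t = 0, p = 1.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ValueError("need at least 2 subjects per condition")
    na, nb = a.shape[0], b.shape[0]
    ma, mb = a.mean(axis=0), b.mean(axis=0)
    va, vb = a.var(axis=0, ddof=1), b.var(axis=0, ddof=1)
    se2 = va / na + vb / nb
    degenerate = se2 == 0
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (ma - mb) / np.sqrt(se2)
        df = se2 ** 2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    t = np.where(degenerate, 0.0, t)
    df = np.where(degenerate, na + nb - 2, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p = np.where(degenerate, 1.0, p)
    return t, p


def _structure(ndim: int) -> np.ndarray:
    # 2-neighbour in 1-D, 4-connectivity in 2-D
    return ndimage.generate_binary_structure(ndim, 1)


def suprathreshold_clusters(p_map: np.ndarray, t_map: np.ndarray,
                            alpha: float = CLUSTER_ALPHA) -> list[ClusterResult]:
    """Connected components of {p < alpha}, split by t sign, sized in pixels."""
    if p_map.shape != t_map.shape:
        raise ValueError("p and t maps must be congruent")
    clusters: list[ClusterResult] = []
    struct = _structure(p_map.ndim)
    for sign, sel in (("positive", t_map > 0), ("negative", t_map < 0)):
        labelled, n = ndimage.label((p_map < alpha) & sel, structure=struct)
        for k in range(1, n + 1):
            mask = labelled == k
            clusters.append(ClusterResult(mask=mask, size_px=int(mask.sum()),
                                          sign=sign))
    clusters.sort(key=lambda c: c.size_px, reverse=True)
    return clusters


def _max_cluster_size(t: np.ndarray, p: np.ndarray, alpha: float,
                      struct: np.ndarray) -> int:
    best = 0
    for sel in (t > 0, t < 0):
        labelled, n = ndimage.label((p < alpha) & sel, structure=struct)
        if n:
            best = max(best, int(np.max(np.bincount(labelled.ravel())[1:])))
    return best


def _sign_patterns(n_subjects: int, n_perm: int, rng: np.random.Generator
                   ) -> tuple[np.ndarray, bool]:
    """Distinct within-subject swap patterns as boolean arrays.

    Returns (patterns, exhaustive). Exhaustive enumeration includes the
    identity; sampled patterns exclude it and never repeat.
    """
    total = 2 ** n_subjects
    if total <= n_perm:
        codes = np.arange(total)
        exhaustive = True
    else:
        codes = rng.choice(total - 1, size=n_perm, replace=False) + 1
        exhaustive = False
    bits = ((codes[:, None] >> np.arange(n_subjects)) & 1).astype(bool)
    return bits, exhaustive


def permutation_cluster_test(a: np.ndarray, b: np.ndarray,
                             n_perm: int = DEFAULT_N_PERM,
                             alpha: float = CLUSTER_ALPHA,
                             seed: int = 0) -> list[ClusterResult]:
    """Score suprathreshold clusters of the paired a-vs-b difference.

    ``a`` and ``b`` are paired subject maps (subject i contributed a_i and
    b_i). The null swaps a_i and b_i within subjects. Sampled permutations
    use p = (1 + #{null >= observed}) / (1 + n_perm); exhaustive
    enumeration uses p = #{null >= observed} / 2^n, which matches a full
    enumeration oracle exactly.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired maps must share a shape")
    n = a.shape[0]
    struct = _structure(a.ndim - 1)
    t_obs, p_obs = welch_t_map(a, b)
    clusters = suprathreshold_clusters(p_obs, t_obs, alpha=alpha)

    rng = np.random.default_rng(seed)
    patterns, exhaustive = _sign_patterns(n, n_perm, rng)
    null = np.empty(patterns.shape[0])
    for i, flip in enumerate(patterns):
        ap = np.where(flip[(...,) + (None,) * (a.ndim - 1)], b, a)
        bp = np.where(flip[(...,) + (None,) * (a.ndim - 1)], a, b)
        tp, pp = welch_t_map(ap, bp)
        null[i] = _max_cluster_size(tp, pp, alpha, struct)

    for c in clusters:
        ge = int(np.sum(null >= c.size_px))
        c.null_sizes = null
        c.p_value = (ge / null.size) if exhaustive else (1 + ge) / (1 + null.size)
        if c.p_value == 0.0:  # guard: exhaustive always has identity >= obs
            c.p_value = 1.0 / null.size
    return clusters


def cluster_power_per_electrode(ersp_by_subject: dict[str, np.ndarray],
                                cluster_mask: np.ndarray,
                                statistic: str = "mean") -> "object":
    """Per-subject, per-electrode summary of dB values inside the cluster.

    ``ersp_by_subject`` maps subject id -> channels x freqs x times dB
    array (trial-averaged). Returns a pandas DataFrame, electrodes x
    subjects. ``statistic`` selects the average (as in the cluster
    definition) or the median variant.
    """
    import pandas as pd

    if not cluster_mask.any():
        raise ValueError("empty cluster mask")
    if statistic not in ("mean", "median"):
        raise ValueError("statistic must be 'mean' or 'median'")
    reducer = np.mean if statistic == "mean" else np.median
    cols = {}
    for subject, arr in ersp_by_subject.items():
        vals = arr[:, cluster_mask]  # channels x pixels
        cols[subject] = reducer(vals, axis=1)
    return pd.DataFrame(cols)
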
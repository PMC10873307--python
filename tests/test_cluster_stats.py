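"""Cluster permutation statistics: Welch maps, cluster finding vs a
flood-fill oracle, exhaustive-permutation agreement, calibration, and
injected-effect detection."""
import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from remstim.cluster_stats import (cluster_power_per_electrode,
                                   permutation_cluster_test,
                                   suprathreshold_clusters, welch_t_map)


def _flood_fill_components(mask):
    """Brute-force 4-connected components of a boolean map (1-D or 2-D)."""
    mask = np.atleast_2d(mask)
    seen = np.zeros_like(mask, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(mask)):
        if seen[start]:
            continue
        stack, comp = [start], set()
        seen[start] = True
        while stack:
            r, c = stack.pop()
            comp.add((r, c))
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < mask.shape[0] and 0 <= cc < mask.shape[1] \
                        and mask[rr, cc] and not seen[rr, cc]:
                    seen[rr, cc] = True
                    stack.append((rr, cc))
        comps.append(comp)
    return comps


class TestWelch:
    def test_identical_groups_zero_t(self):
        a = np.random.default_rng(0).normal(size=(5, 4, 4))
        t, p = welch_t_map(a, a.copy())
        np.testing.assert_allclose(t, 0.0)
        np.testing.assert_allclose(p, 1.0)

    def test_closed_form_oracle(self):
        """a = {1,2,3}, b = {4,5,6} per pixel: Welch t = -3/sqrt(2/3)."""
        a = np.array([1.0, 2.0, 3.0])[:, None]
        b = np.array([4.0, 5.0, 6.0])[:, None]
        t, p = welch_t_map(a, b)
        se = np.sqrt(1.0 / 3 + 1.0 / 3)  # var 1, n 3 each
        assert t[0] == pytest.approx(-3.0 / se)
        # equal variances: Welch df equals pooled df and t equals Student t
        t_s, p_s = stats.ttest_ind(a[:, 0], b[:, 0], equal_var=True)
        assert t[0] == pytest.approx(t_s)
        assert p[0] == pytest.approx(p_s)

    def test_matches_scipy_welch_on_random_maps(self, rng):
        a = rng.normal(size=(6, 3, 5))
        b = rng.normal(1.0, 2.0, size=(8, 3, 5))
        t, p = welch_t_map(a, b)
        t_ref, p_ref = stats.ttest_ind(a, b, axis=0, equal_var=False)
        np.testing.assert_allclose(t, t_ref, rtol=1e-10)
        np.testing.assert_allclose(p, p_ref, rtol=1e-10)

    def test_degenerate_pixels_flagged_p_one(self):
        a = np.ones((4, 2))
        b = np.ones((4, 2))
        b[:, 1] = [0, 1, 2, 3]
        t, p = welch_t_map(a, b)
        assert p[0] == 1.0 and t[0] == 0.0

    def test_too_few_subjects_rejected(self):
        with pytest.raises(ValueError):
            welch_t_map(np.ones((1, 3)), np.ones((3, 3)))


class TestClusterFinding:
    def test_no_significant_pixels(self):
        p = np.full((5, 5), 0.5)
        t = np.ones((5, 5))
        assert suprathreshold_clusters(p, t) == []

    def test_toy_two_blob_map(self):
        p = np.ones((5, 5))
        t = np.zeros((5, 5))
        for r, c in ((0, 0), (0, 1), (1, 0)):         # blob of 3
            p[r, c], t[r, c] = 0.01, 2.0
        for r, c in ((3, 3), (3, 4), (4, 3), (4, 4)):  # blob of 4
            p[r, c], t[r, c] = 0.01, -2.0
        out = suprathreshold_clusters(p, t)
        assert sorted((c.size_px, c.sign) for c in out) == \
            [(3, "positive"), (4, "negative")]

    def test_single_pixel_cluster(self):
        p = np.ones((3, 3))
        t = np.zeros((3, 3))
        p[1, 1], t[1, 1] = 0.01, -1.0
        out = suprathreshold_clusters(p, t)
        assert len(out) == 1 and out[0].size_px == 1 and out[0].sign == "negative"

    def test_opposite_signs_not_merged(self):
        p = np.full((1, 4), 0.01)
        t = np.array([[1.0, 1.0, -1.0, -1.0]])
        out = suprathreshold_clusters(p, t)
        assert sorted(c.size_px for c in out) == [2, 2]

    def test_agrees_with_flood_fill_oracle_on_random_maps(self, rng):
        """1,000 random small maps: the sorted per-sign component sizes
        match a brute-force flood fill."""
        for _ in range(1000):
            shape = (rng.integers(1, 7), rng.integers(1, 7))
            p = rng.random(shape)
            t = rng.normal(size=shape)
            out = suprathreshold_clusters(p, t, alpha=0.3)
            got = sorted((c.sign, c.size_px) for c in out)
            want = []
            for sign, sel in (("positive", t > 0), ("negative", t < 0)):
                for comp in _flood_fill_components((p < 0.3) & sel):
                    want.append((sign, len(comp)))
            assert got == sorted(want)


class TestPermutationTest:
    def test_exchangeable_degenerate_p_one(self, rng):
        a = rng.normal(size=(6, 4, 5))
        out = permutation_cluster_test(a, a.copy(), n_perm=100, seed=0)
        assert all(c.p_value == 1.0 for c in out)

    def test_exhaustive_matches_enumeration_oracle(self, rng):
        """n = 4 subjects: p equals the full 16-pattern enumeration."""
        a = rng.normal(0.0, 1.0, size=(4, 3, 6)) + 1.5
        b = rng.normal(size=(4, 3, 6))
        out = permutation_cluster_test(a, b, n_perm=1600, seed=1)
        assert out, "expected at least one cluster"

        null = []
        for flips in itertools.product([False, True], repeat=4):
            f = np.array(flips)[:, None, None]
            ap, bp = np.where(f, b, a), np.where(f, a, b)
            t, p = welch_t_map(ap, bp)
            sizes = [c.size_px for c in suprathreshold_clusters(p, t)]
            null.append(max(sizes) if sizes else 0)
        null = np.array(null)
        for c in out:
            assert c.p_value == pytest.approx(np.mean(null >= c.size_px))

    def test_p_value_bounds_and_monotonicity(self, rng):
        a = rng.normal(1.0, 1.0, size=(8, 4, 6))
        b = rng.normal(size=(8, 4, 6))
        out = permutation_cluster_test(a, b, n_perm=200, seed=2)
        sizes = [c.size_px for c in out]
        ps = [c.p_value for c in out]
        for s, p in zip(sizes, ps):
            assert 1.0 / (200 + 1) <= p <= 1.0
        # larger observed cluster -> no larger p
        order = np.argsort(sizes)
        assert all(ps[order[i]] >= ps[order[i + 1]] - 1e-12
                   for i in range(len(order) - 1))

    def test_mismatched_shapes_rejected(self, rng):
        with pytest.raises(ValueError):
            permutation_cluster_test(rng.normal(size=(4, 3)),
                                     rng.normal(size=(4, 4)))


class TestClusterPower:
    def _mask(self):
        mask = np.zeros((4, 5), dtype=bool)
        mask[1, 1] = mask[1, 2] = mask[2, 1] = True
        return mask

    def test_constant_field(self):
        mask = self._mask()
        arr = np.full((3, 4, 5), 2.5)
        out = cluster_power_per_electrode({"s1": arr}, mask)
        np.testing.assert_allclose(out["s1"], 2.5)

    def test_mean_and_median_variants(self):
        mask = self._mask()
        arr = np.zeros((1, 4, 5))
        arr[0, 1, 1], arr[0, 1, 2], arr[0, 2, 1] = 1.0, 2.0, 6.0
        assert cluster_power_per_electrode({"s": arr}, mask, "mean")["s"][0] \
            == pytest.approx(3.0)
        assert cluster_power_per_electrode({"s": arr}, mask, "median")["s"][0] \
            == pytest.approx(2.0)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            cluster_power_per_electrode({"s": np.zeros((1, 2, 2))},
                                        np.zeros((2, 2), dtype=bool))


class TestInjectionDetection:
    def test_injected_effects_detected_in_90pct_of_runs(self):
        """Synthetic beta-increase/theta-decrease experiments at the study's
        cohort size (19 paired subjects): significant clusters overlap the
        injected windows in >= 90% of seeded runs."""
        from remstim.evoked import compute_ersp, epoch_trials
        from remstim.synth import generate_eeg_with_responses
        from remstim.types import Hypnogram, SyntheticGroundTruth

        fs, n_trials, n_subj = 125.0, 80, 19
        freqs = np.arange(2, 30.1, 1.0)
        n_runs = 50
        hits_beta = hits_theta = 0
        gt_on = SyntheticGroundTruth()
        n_ep = int(np.ceil((n_trials * 5.6 + 12) / 30))
        hyp = Hypnogram(stages=["R"] * n_ep)
        clicks = np.arange(5.0, hyp.duration_s - 5.5, 5.6)[:n_trials]
        for run in range(n_runs):
            maps = {"stm": [], "cnt": []}
            for s in range(n_subj):
                for cond, inject in (("stm", True), ("cnt", False)):
                    gt = gt_on if inject else SyntheticGroundTruth(
                        beta_amplitude_db=0, theta_amplitude_db=0,
                        p2_amplitude_uv=0, negativity_amplitude_uv=0)
                    eeg = generate_eeg_with_responses(
                        hyp, clicks, gt, ["Cz"], fs=fs,
                        seed=run * 1000 + s * 2 + (0 if inject else 1))
                    ts = epoch_trials(eeg, clicks, hyp)
                    ersp = compute_ersp(ts, freqs_hz=freqs, decim=5)
                    maps[cond].append(ersp.values.mean(axis=(0, 1)))
            stm, cnt = np.array(maps["stm"]), np.array(maps["cnt"])
            out = permutation_cluster_test(stm, cnt, n_perm=400, seed=run)
            fsel_b = (freqs >= 15) & (freqs <= 25)
            fsel_t = (freqs >= 4) & (freqs <= 8)
            tsel_b = (ersp.times >= 0.2) & (ersp.times <= 1.4)
            tsel_t = (ersp.times >= 0.7) & (ersp.times <= 1.5)
            found_b = found_t = False
            for c in out:
                if c.p_value >= 0.05:
                    continue
                if c.sign == "positive" and c.mask[np.ix_(fsel_b, tsel_b)].any():
                    found_b = True
                if c.sign == "negative" and c.mask[np.ix_(fsel_t, tsel_t)].any():
                    found_t = True
            hits_beta += found_b
            hits_theta += found_t
        assert hits_beta >= 0.9 * n_runs, f"beta detected in {hits_beta}/{n_runs}"
        assert hits_theta >= 0.9 * n_runs, f"theta detected in {hits_theta}/{n_runs}"
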
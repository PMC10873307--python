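"""Statistical layer: normality gate, paired tests, gain models, robust
fits, FDR, correlations, and the paired-t power analysis."""
import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from remstim.stats_models import (achieved_power_paired_t, bh_fdr,
                                  between_condition_diff, correlate,
                                  electrode_power_regressions, huber_fit,
                                  multivar_gain_model, paired_compare,
                                  power_analysis_paired_t, shapiro_francia)


class TestShapiroFrancia:
    def test_quantile_spaced_data_near_one(self):
        x = stats.norm.ppf((np.arange(1, 51) - 0.375) / 50.25)
        w, p = shapiro_francia(x)
        assert w > 0.999

    def test_matches_r_nortest_reference(self):
        """Frozen oracle from R's nortest::sf.test on a fixed vector."""
        x = [2.1, -0.7, 0.3, 1.8, -1.2, 0.5, 0.9, -0.4, 2.5, 0.1, -0.9, 1.1,
             0.6, -2.0, 0.2, 3.4, 0.8, -0.1, 1.4, 0.05]
        w, p = shapiro_francia(x)
        assert w == pytest.approx(0.9865549910, abs=1e-9)
        assert p == pytest.approx(0.9685880004, abs=1e-9)

    def test_power_against_exponential(self):
        hits = sum(shapiro_francia(
            np.random.default_rng(s).exponential(size=50))[1] < 0.05
            for s in range(100))
        assert hits >= 95

    def test_w_bounded_by_one(self):
        for s in range(20):
            w, _ = shapiro_francia(np.random.default_rng(s).normal(size=30))
            assert 0 < w <= 1

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError):
            shapiro_francia(np.ones(10))


class TestPairedCompare:
    def test_shifted_normal_pairs_use_t(self):
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, 20)
        y = x + 5 + rng.normal(0, 0.5, 20)
        res = paired_compare(x, y)
        assert res.test == "paired_t"
        assert res.p_value < 1e-6

    def test_wilcoxon_exact_matches_enumeration(self):
        """n = 6 non-normal-gated fixture: exact signed-rank p equals full
        2^6 sign enumeration."""
        diff = np.array([1.0, 2.0, 3.0, 4.0, 5.0, -0.5])
        ranks = stats.rankdata(np.abs(diff))
        w_obs = ranks[diff > 0].sum()
        total = 0
        extreme = 0
        for signs in itertools.product([1, -1], repeat=6):
            w = ranks[np.array(signs) > 0].sum()
            stat = min(w, ranks.sum() - w)
            obs = min(w_obs, ranks.sum() - w_obs)
            extreme += stat <= obs
            total += 1
        p_enum = extreme / total
        res = stats.wilcoxon(diff, method="exact")
        assert res.pvalue == pytest.approx(p_enum)

    def test_identical_vectors_degenerate(self):
        x = np.arange(10.0)
        res = paired_compare(x, x.copy())
        assert res.degenerate and res.p_value == 1.0 and res.cohens_d == 0.0

    def test_logit_transform_applied_for_proportions(self):
        rng = np.random.default_rng(1)
        x = rng.uniform(0.4, 0.6, 15)
        y = np.clip(x + 0.2, 0.05, 0.95)
        res = paired_compare(x, y, proportion_flag=True)
        assert res.transform == "logit"
        assert res.p_value < 0.01

    def test_skewed_differences_fall_back_to_wilcoxon(self):
        rng = np.random.default_rng(2)
        x = np.zeros(40)
        y = rng.exponential(1.0, 40) ** 3
        res = paired_compare(x, y)
        assert res.test == "wilcoxon_signed_rank"


class TestGainModel:
    def test_noiseless_recovery_of_printed_coefficients(self):
        """Data generated exactly from gain = 13.5 + 20.5 C - 0.66 tR is
        recovered to machine precision."""
        rng = np.random.default_rng(1)
        C = rng.integers(0, 2, 40).astype(float)
        tR = rng.uniform(10, 60, 40)
        y = 13.5 + 20.5 * C - 0.66 * tR
        fit = multivar_gain_model(y, C, tR)
        np.testing.assert_allclose(fit.coefficients, [13.5, 20.5, -0.66],
                                   rtol=1e-10)
        assert fit.r_squared == pytest.approx(1.0)

    def test_null_slope_coverage(self):
        """beta2 = 0 truth: the 95% CI covers 0 in about 95% of 500 runs."""
        rng = np.random.default_rng(4)
        covered = 0
        n_runs = 500
        for _ in range(n_runs):
            C = rng.integers(0, 2, 200).astype(float)
            tR = rng.uniform(10, 60, 200)
            y = 5.0 + 10.0 * C + rng.normal(0, 8, 200)
            fit = multivar_gain_model(y, C, tR)
            half = stats.t.ppf(0.975, fit.df[1]) * fit.std_errors[2]
            covered += abs(fit.coefficients[2]) <= half
        lo, hi = stats.binom.ppf([0.005, 0.995], n_runs, 0.95)
        assert lo <= covered <= hi

    def test_constant_gain_null_model(self):
        fit = multivar_gain_model(np.full(10, 3.0),
                                  np.arange(10) % 2, np.arange(10.0))
        assert fit.r_squared == 0.0
        assert fit.f_pvalue == 1.0

    def test_collinear_design_rejected(self):
        C = np.arange(10.0)
        with pytest.raises(ValueError):
            multivar_gain_model(np.arange(10.0), C, 2 * C)


def _proposal2_scale(r, n, p, d=2.5, tol=1e-8, maxiter=100):
    """Huber's proposal-2 scale: fixpoint of
    s^2 = (1 / (n h)) * sum(chi(r / s)) * s^2, chi(x) = min(x^2, d^2) / 2,
    with the degrees-of-freedom consistency constant h."""
    phi_d = np.exp(-0.5 * d * d) / np.sqrt(2 * np.pi)
    h = (n - p) / n * (d * d + (1 - d * d) * stats.norm.cdf(d)
                       - 0.5 - d * phi_d)
    s = np.median(np.abs(r)) / 0.6744897501960817
    for _ in range(maxiter):
        chi = np.minimum((r / s) ** 2, d * d) / 2.0
        s_new = np.sqrt(np.sum(chi) * s * s / (n * h))
        if abs(s_new - s) <= tol:
            return s_new
        s = s_new
    return s


def _irls_huber_oracle(X, y, c=1.345, iters=200):
    """Independent IRLS with Huber weights and joint proposal-2 scale."""
    Xd = np.column_stack([np.ones(len(y)), X])
    n, p = Xd.shape
    beta = np.linalg.lstsq(Xd, y, rcond=None)[0]
    for _ in range(iters):
        r = y - Xd @ beta
        scale = _proposal2_scale(r, n, p)
        if scale == 0:
            break
        u = r / (scale * c)
        w = np.where(np.abs(u) <= 1, 1.0, 1.0 / np.abs(u))
        sw = np.sqrt(w)
        beta_new = np.linalg.lstsq(Xd * sw[:, None], y * sw, rcond=None)[0]
        if np.max(np.abs(beta_new - beta)) < 1e-12:
            beta = beta_new
            break
        beta = beta_new
    return beta


class TestHuber:
    def test_exact_line_equals_ols(self):
        x = np.linspace(0, 10, 20)
        fit = huber_fit(x[:, None], 2 + 3 * x)
        np.testing.assert_allclose(fit.coefficients, [2.0, 3.0], atol=1e-8)

    def test_outlier_resistance_beats_ols(self):
        import statsmodels.api as sm

        x = np.linspace(0, 10, 20)
        y = 2 + 3 * x
        y[5] += 100.0
        hub = huber_fit(x[:, None], y)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        assert abs(hub.coefficients[1] - 3.0) < abs(ols.params[1] - 3.0)

    def test_matches_independent_irls_oracle(self):
        rng = np.random.default_rng(9)
        x = rng.uniform(0, 5, 10)
        y = 1.0 + 2.0 * x + rng.normal(0, 0.5, 10)
        y[3] += 8.0
        fit = huber_fit(x[:, None], y)
        oracle = _irls_huber_oracle(x, y)
        np.testing.assert_allclose(fit.coefficients, oracle, atol=1e-3)

    def test_large_tuning_constant_approaches_ols(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(5)
        x = rng.uniform(0, 5, 30)
        y = 1 + 2 * x + rng.standard_cauchy(30)
        hub = huber_fit(x[:, None], y, tuning_c=1e6)
        ols = sm.OLS(y, sm.add_constant(x)).fit()
        np.testing.assert_allclose(hub.coefficients, ols.params, atol=1e-5)

    def test_underdetermined_rejected(self):
        with pytest.raises(ValueError):
            huber_fit(np.ones((2, 2)), np.ones(2))


class TestElectrodeRegressions:
    def test_null_false_discovery_proportion_controlled(self):
        """Power unrelated to gain: mean false-discovery proportion over
        null simulations stays at or below q = 0.05."""
        rng = np.random.default_rng(11)
        fdps = []
        for _ in range(300):
            power = pd.DataFrame(rng.normal(0, 0.1, (21, 12)),
                                 index=[f"E{i}" for i in range(21)])
            gain = rng.normal(0, 10, 12)
            res = electrode_power_regressions(power, gain)
            n_rej = len(res["significant"])
            fdps.append(1.0 if n_rej > 0 else 0.0)
        assert np.mean(fdps) <= 0.05 + 2 * np.sqrt(0.05 * 0.95 / 300)

    def test_single_carrier_electrode_survives(self):
        """One electrode with the strong published slope (87.1 %/dB) against
        20 null electrodes survives FDR in >= 90% of runs."""
        rng = np.random.default_rng(12)
        wins = 0
        n_runs = 25
        for _ in range(n_runs):
            power = pd.DataFrame(rng.normal(0, 0.1, (21, 19)),
                                 index=[f"E{i}" for i in range(21)])
            gain = 87.1 * power.loc["E0"].to_numpy() + rng.normal(0, 4, 19)
            res = electrode_power_regressions(power, gain)
            wins += "E0" in res["significant"]
        assert wins >= 0.9 * n_runs

    def test_constant_power_gives_empty_mask(self):
        power = pd.DataFrame(np.ones((21, 8)),
                             index=[f"E{i}" for i in range(21)])
        res = electrode_power_regressions(power, np.arange(8.0))
        assert res["significant"] == [] and res["pooled"] is None


class TestBhFdr:
    def test_step_up_walked_by_hand(self):
        mask = bh_fdr([0.01, 0.02, 0.03, 0.2], q=0.05)
        np.testing.assert_array_equal(mask, [True, True, True, False])

    def test_all_ones_rejects_nothing(self):
        assert not bh_fdr(np.ones(10)).any()

    def test_matches_brute_force_on_random_vectors(self, rng):
        """1,000 random p-vectors against a literal step-up evaluation."""
        for _ in range(1000):
            m = rng.integers(1, 12)
            p = np.round(rng.random(m), 3)
            got = bh_fdr(p, q=0.1)
            order = np.argsort(p, kind="stable")
            k_best = 0
            for k in range(1, m + 1):
                if p[order[k - 1]] <= k * 0.1 / m:
                    k_best = k
            want = np.zeros(m, bool)
            want[order[:k_best]] = True
            np.testing.assert_array_equal(got, want)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=2, max_size=20))
    def test_rejection_mask_monotone_in_p(self, ps):
        p = np.array(ps)
        mask = bh_fdr(p)
        if mask.any() and (~mask).any():
            assert p[mask].max() <= p[~mask].min()


class TestDifferencesAndCorrelation:
    def test_equal_powers_zero_db(self):
        assert between_condition_diff(3.0, 3.0, "power") == pytest.approx(0.0)

    def test_doubled_power_is_3db(self):
        assert between_condition_diff(1.0, 2.0, "power") == \
            pytest.approx(3.0103, abs=1e-4)

    def test_time_sign_convention(self):
        assert between_condition_diff(10.0, 8.0, "time") == pytest.approx(2.0)

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            between_condition_diff(0.0, 1.0, "power")

    def test_correlation_identity_and_reflection(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert correlate(x, x)["rho"] == pytest.approx(1.0)
        assert correlate(x, -x)["rho"] == pytest.approx(-1.0)

    def test_correlation_matches_covariance_formula(self):
        x = np.array([1.0, 2.0, 4.0, 4.5, 7.0])
        y = np.array([2.0, 1.0, 5.0, 6.0, 6.5])
        rho = correlate(x, y)["rho"]
        want = np.cov(x, y, ddof=1)[0, 1] / (x.std(ddof=1) * y.std(ddof=1))
        assert rho == pytest.approx(want, rel=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            correlate(np.ones(5), np.arange(5.0))


class TestPowerAnalysis:
    def test_published_design_sample_size(self):
        assert power_analysis_paired_t(0.7, 0.05, 0.80) == 19

    def test_monotone_in_effect_size(self):
        assert power_analysis_paired_t(1.4, 0.05, 0.80) < \
            power_analysis_paired_t(0.7, 0.05, 0.80)

    def test_bracketing_oracle(self):
        """The returned N attains the target and N-1 does not, checked with
        the noncentral-t CDF directly."""
        n = power_analysis_paired_t(0.5, 0.05, 0.9)
        for m, ok in ((n, True), (n - 1, False)):
            df, nc = m - 1, 0.5 * np.sqrt(m)
            tc = stats.t.ppf(0.975, df)
            pw = 1 - stats.nct.cdf(tc, df, nc) + stats.nct.cdf(-tc, df, nc)
            assert bool(pw >= 0.9) == ok
        assert achieved_power_paired_t(0.5, n) >= 0.9

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            power_analysis_paired_t(-1.0)
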
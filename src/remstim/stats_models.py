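"""The study's statistical layer.

Normality-gated paired comparisons (Shapiro-Francia -> paired t or
Wilcoxon signed-rank, with a logit transform for proportions), the
multivariable overnight-gain models (gain ~ condition + sleep-stage time),
electrode-wise robust (Huber) regressions of cluster power on performance
gain with Benjamini-Hochberg FDR control, the between-condition difference
conventions, Pearson correlations, and the exact noncentral-t power
analysis for paired designs.

Condition coding throughout: CNT = 0, STM = 1.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import PairedComparison, RegressionFit

HUBER_TUNING = 1.345
NORMALITY_ALPHA = 0.05


def shapiro_francia(x) -> tuple[float, float]:
    """Shapiro-Francia normality test.

    W' is the squared correlation between the sorted sample and the
    expected standard-normal order statistics (Blom scores); the p-value
    uses the Royston log-transform normal approximation, valid for
    5 <= n <= 5000.
    """
    x = np.sort(np.asarray(x, dtype=float))
    n = x.size
    if not 5 <= n <= 5000:
        raise ValueError("Shapiro-Francia requires 5 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("constant sample")
    m = stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
    w = np.corrcoef(x, m)[0, 1] ** 2
    u, v = np.log(n), np.log(np.log(n))
    mu = -1.2725 + 1.0521 * (v - u)
    sigma = 1.0308 - 0.26758 * (v + 2.0 / u)
    z = (np.log(1.0 - w) - mu) / sigma
    return float(w), float(stats.norm.sf(z))


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("proportions must lie strictly in (0, 1) for logit")
    return np.log(p / (1 - p))


def paired_compare(x, y, proportion_flag: bool = False) -> PairedComparison:
    """Paired comparison gated on normality of the differences.

    Proportions are logit-transformed first. If Shapiro-Francia on the
    differences gives p >= 0.05 the comparison is a paired t-test, else a
    Wilcoxon signed-rank test (exact for n <= 25, zeros dropped). Also
    returns paired Cohen's d = mean(diff) / sd(diff).
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    transform = "none"
    if proportion_flag:
        x, y = _logit(x), _logit(y)
        transform = "logit"
    diff = x - y
    if np.all(diff == 0):
        return PairedComparison(test="paired_t", statistic=0.0, p_value=1.0,
                                cohens_d=0.0, normality_w=float("nan"),
                                normality_p=float("nan"), transform=transform,
                                degenerate=True)
    w, w_p = shapiro_francia(diff)
    sd = diff.std(ddof=1)
    d = float(diff.mean() / sd) if sd > 0 else 0.0
    if w_p >= NORMALITY_ALPHA:
        t, p = stats.ttest_rel(x, y)
        return PairedComparison(test="paired_t", statistic=float(t),
                                p_value=float(p), cohens_d=d,
                                normality_w=w, normality_p=w_p,
                                transform=transform)
    nz = diff[diff != 0]
    mode = "exact" if nz.size <= 25 else "approx"
    res = stats.wilcoxon(nz, method=mode)
    return PairedComparison(test="wilcoxon_signed_rank",
                            statistic=float(res.statistic),
                            p_value=float(res.pvalue), cohens_d=d,
                            normality_w=w, normality_p=w_p,
                            transform=transform)


def _fit_to_result(res, n: int, method: str, converged: bool = True
                   ) -> RegressionFit:
    r2 = getattr(res, "rsquared", float("nan"))
    f = getattr(res, "fvalue", float("nan"))
    fp = getattr(res, "f_pvalue", float("nan"))
    df = (int(getattr(res, "df_model", 0)), int(getattr(res, "df_resid", 0)))
    return RegressionFit(coefficients=np.asarray(res.params, float),
                         std_errors=np.asarray(res.bse, float),
                         p_values=np.asarray(res.pvalues, float),
                         r_squared=float(r2) if r2 is not None else float("nan"),
                         f_statistic=float(f) if f is not None else float("nan"),
                         f_pvalue=float(fp) if fp is not None else float("nan"),
                         df=df, n=n, method=method, converged=converged)


def multivar_gain_model(gain, condition_codes, stage_minutes) -> RegressionFit:
    """OLS fit of gain = b0 + b1 * condition + b2 * stage_minutes."""
    y = np.asarray(gain, float)
    X = np.column_stack([np.asarray(condition_codes, float),
                         np.asarray(stage_minutes, float)])
    if y.size <= 3:
        raise ValueError("need n > 3")
    Xd = sm.add_constant(X)
    if np.linalg.matrix_rank(Xd) < Xd.shape[1]:
        raise ValueError("collinear design matrix")
    res = sm.OLS(y, Xd).fit()
    fit = _fit_to_result(res, y.size, "OLS")
    if np.ptp(y) == 0:  # constant response: no variance to explain
        fit.r_squared, fit.f_statistic, fit.f_pvalue = 0.0, 0.0, 1.0
    else:
        fit.r_squared = float(res.rsquared)
    return fit


def huber_fit(X, y, tuning_c: float = HUBER_TUNING, tol: float = 1e-8,
              max_iter: int = 100) -> RegressionFit:
    """Robust linear fit with Huber's M-estimator (IRLS).

    A constant column is prepended. Scale is estimated jointly by Huber's
    proposal 2 (rather than the MAD), and coefficient p-values use a t
    reference with n - k degrees of freedom: both choices keep the
    electrode-wise slope tests calibrated at the small per-subject sample
    sizes this design produces, which the FDR step downstream relies on.
    Iteration stops when coefficients change by < ``tol``.
    """
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1 and X.shape[1] > 1 and np.asarray(y).size == X.shape[1]:
        X = X.T
    y = np.asarray(y, float)
    if y.size <= X.shape[1]:
        raise ValueError("need more observations than parameters")
    Xd = sm.add_constant(X)
    model = sm.RLM(y, Xd, M=sm.robust.norms.HuberT(t=tuning_c))
    try:
        res = model.fit(maxiter=max_iter, tol=tol, conv="coefs",
                        scale_est=sm.robust.scale.HuberScale())
    except (ValueError, ZeroDivisionError):
        # degenerate residual distribution: fall back to the MAD scale
        res = model.fit(maxiter=max_iter, tol=tol, conv="coefs")
    converged = bool(np.all(np.isfinite(res.params)))
    df_resid = y.size - Xd.shape[1]
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.asarray(res.params) / np.asarray(res.bse)
    pvals = 2.0 * stats.t.sf(np.abs(tvals), df_resid)
    fit = _fit_to_result(res, y.size, "Huber", converged=converged)
    fit.p_values = np.where(np.isfinite(tvals), pvals, np.nan)
    fit.r_squared = float("nan")  # not defined for M-estimation
    fit.f_statistic = float("nan")
    fit.f_pvalue = float("nan")
    return fit


def bh_fdr(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection mask at level q.

    Finds the largest k with p_(k) <= k q / m and rejects the k smallest
    p-values.
    """
    p = np.asarray(p_values, float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    thresh = np.arange(1, m + 1) * q / m
    below = p[order] <= thresh
    mask = np.zeros(m, dtype=bool)
    if below.any():
        k = int(np.max(np.flatnonzero(below))) + 1
        mask[order[:k]] = True
    return mask


def electrode_power_regressions(power: pd.DataFrame, gain: np.ndarray,
                                q: float = 0.05) -> dict:
    """Per-electrode Huber regressions of performance gain on cluster power.

    ``power`` is electrodes x subjects (dB); ``gain`` the matching subject
    gains (%). Slope p-values are BH-corrected across electrodes. Returns
    the per-electrode fits, the survivor mask, and a pooled Huber fit of
    gain on the mean power across surviving electrodes.
    """
    gain = np.asarray(gain, float)
    if gain.size < 4:
        raise ValueError("need at least 4 subjects")
    fits: dict[str, RegressionFit] = {}
    pvals = []
    electrodes = list(power.index)
    for el in electrodes:
        x = power.loc[el].to_numpy(dtype=float)
        if np.ptp(x) == 0:
            fits[el] = None
            pvals.append(1.0)
            continue
        fit = huber_fit(x[:, None], gain)
        fits[el] = fit
        pvals.append(float(fit.p_values[1]))
    pvals = np.array(pvals)
    fitted = np.array([fits[el] is not None for el in electrodes])
    mask = np.zeros(len(electrodes), dtype=bool)
    if fitted.any():
        mask[fitted] = bh_fdr(pvals[fitted], q=q)
    significant = [el for el, m in zip(electrodes, mask) if m]
    pooled = None
    if significant:
        mean_power = power.loc[significant].mean(axis=0).to_numpy(dtype=float)
        pooled = huber_fit(mean_power[:, None], gain)
    return {"fits": fits, "p_values": dict(zip(electrodes, pvals)),
            "mask": dict(zip(electrodes, mask)),
            "significant": significant, "pooled": pooled}


def between_condition_diff(cnt_value, stm_value, kind: str):
    """Between-condition difference with the study's sign conventions.

    time/performance: CNT - STM (positive = larger in CNT... the study
    reports gains such that positive differences favour STM when the STM
    value is subtracted; the convention here is verbatim CNT - STM).
    power: 10 log10(STM / CNT) dB (positive = more power in STM).
    """
    cnt = np.asarray(cnt_value, float)
    stm = np.asarray(stm_value, float)
    if kind in ("time", "performance"):
        return cnt - stm
    if kind == "power":
        if np.any(cnt <= 0) or np.any(stm <= 0):
            raise ValueError("powers must be positive")
        return 10.0 * np.log10(stm / cnt)
    raise ValueError(f"unknown kind {kind!r}")


def correlate(x, y, fdr_group: list | None = None, q: float = 0.05) -> dict:
    """Pearson correlation with t-based p; optional BH correction within a
    family of p-values supplied via ``fdr_group``."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.size < 3:
        raise ValueError("need n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    rho, p = stats.pearsonr(x, y)
    out = {"rho": float(rho), "p": float(p), "p_corrected": None}
    if fdr_group is not None:
        family = np.array(list(fdr_group) + [p])
        m = family.size
        # BH adjusted p-value for the last entry
        order = np.argsort(family)
        ranks = np.empty(m, int)
        ranks[order] = np.arange(1, m + 1)
        adj = np.minimum.accumulate((family[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        out["p_corrected"] = float(np.clip(adj[ranks[-1] - 1], 0, 1))
    return out


def power_analysis_paired_t(d: float, alpha: float = 0.05,
                            power: float = 0.80, n_max: int = 10000) -> int:
    """Smallest N giving the requested power for a two-sided paired t-test.

    Exact noncentral-t evaluation: with N pairs, the test statistic under
    the alternative is noncentral t with df = N - 1 and noncentrality
    d * sqrt(N).
    """
    if d <= 0 or not (0 < alpha < 1) or not (0 < power < 1):
        raise ValueError("require d > 0 and alpha, power in (0, 1)")
    for n in range(2, n_max + 1):
        if achieved_power_paired_t(d, n, alpha) >= power:
            return n
    raise ValueError("requested power unreachable within n_max")


def achieved_power_paired_t(d: float, n: int, alpha: float = 0.05) -> float:
    """Exact power of the two-sided one-sample t-test on paired differences."""
    df = n - 1
    nc = d * np.sqrt(n)
    tcrit = stats.t.ppf(1 - alpha / 2, df)
    return float(1 - stats.nct.cdf(tcrit, df, nc) + stats.nct.cdf(-tcrit, df, nc))
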
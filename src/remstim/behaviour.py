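"""Scoring of the three behavioural tasks and the overnight gain.

PVT: mean reaction time over valid trials (RT within [100, 500] ms).
VDT: threshold SOA at which a fitted cumulative-Gaussian psychometric
curve reaches 80% accuracy on the orientation judgement, after removing
trials with an incorrect letter response. Guess rate is fixed at 0.5
(two-alternative judgement); the lapse rate is fitted in [0, 0.06].
MTT: mean log on-path time after removing trials more than 3.5 group-SDs
from the group mean log-time.
Overnight gain = 100 x (evening - morning) / evening on the task's
performance value, applied verbatim with no per-task sign flipping.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import ndtr
from scipy.stats import norm

from .types import BehaviouralSession, TaskScore

PVT_VALID_MS = (100.0, 500.0)
VDT_CRITERION = 0.80
VDT_GUESS = 0.5
VDT_LAPSE_MAX = 0.06
MTT_OUTLIER_SD = 3.5


def pvt_score(trials: pd.DataFrame, subject_id: str = "", condition: str = "",
              session: str = "") -> TaskScore:
    """Mean RT (ms) over trials with RT in the closed interval [100, 500] ms."""
    rt = np.asarray(trials["rt_ms"], dtype=float)
    valid = rt[(rt >= PVT_VALID_MS[0]) & (rt <= PVT_VALID_MS[1])]
    if valid.size == 0:
        raise ValueError("no valid PVT trials")
    return TaskScore(task="PVT", subject_id=subject_id, condition=condition,
                     session=session, value=float(valid.mean()),
                     n_valid_trials=int(valid.size))


def _psychometric(soa, mu, sigma, lam):
    # ndtr instead of norm.cdf: this sits inside the optimizer's hot loop
    return VDT_GUESS + (1 - VDT_GUESS - lam) * ndtr((soa - mu) / sigma)


def _vdt_negloglik(params, soa, n, k):
    # binomial aggregation per SOA level: same likelihood as the Bernoulli
    # trials up to an additive constant
    mu, log_sigma, lam = params
    lam_c = np.clip(lam, 0.0, VDT_LAPSE_MAX)
    penalty = 1e4 * (lam - lam_c) ** 2  # soft box constraint on the lapse rate
    p = _psychometric(soa, mu, np.exp(log_sigma), lam_c)
    p = np.clip(p, 1e-9, 1 - 1e-9)
    return -np.sum(k * np.log(p) + (n - k) * np.log1p(-p)) + penalty


def fit_psychometric(soa_levels: np.ndarray, n_trials: np.ndarray,
                     n_correct: np.ndarray, n_starts: int = 3) -> dict:
    """ML fit of the cumulative-Gaussian psychometric curve to per-SOA
    binomial counts. Returns parameters, the 80% threshold, and diagnostics."""
    best = None
    starts = (np.percentile(soa_levels, 25), np.median(soa_levels),
              np.percentile(soa_levels, 75))[:max(n_starts, 1)]
    for mu0 in starts:
        res = minimize(_vdt_negloglik, x0=[mu0, np.log(30.0), 0.02],
                       args=(soa_levels, n_trials, n_correct),
                       method="Nelder-Mead",
                       options={"xatol": 1e-4, "fatol": 1e-7, "maxiter": 600})
        if best is None or res.fun < best.fun:
            best = res
    mu = float(best.x[0])
    sigma = float(np.exp(best.x[1]))
    lam = float(np.clip(best.x[2], 0, VDT_LAPSE_MAX))
    top = 1 - VDT_GUESS - lam
    threshold = mu + sigma * norm.ppf((VDT_CRITERION - VDT_GUESS) / top)
    return {"mu": mu, "sigma": sigma, "lapse": lam,
            "threshold": float(threshold),
            "neg_loglik": float(best.fun), "converged": bool(best.success)}


def vdt_threshold(trials: pd.DataFrame, subject_id: str = "", condition: str = "",
                  session: str = "") -> TaskScore:
    """Threshold SOA (ms) where the fitted psychometric curve reaches 80%.

    Maximum-likelihood fit of gamma + (1 - gamma - lambda) * Phi((SOA - mu)
    / sigma) to the Bernoulli orientation outcomes; trials with an
    incorrect letter response are removed first. The score is flagged when
    the fit fails or the threshold escapes [min SOA / 2, 2 * max SOA].
    """
    kept = trials[trials["letter_correct"].astype(bool)]
    soa = np.asarray(kept["soa_ms"], dtype=float)
    correct = np.asarray(kept["orientation_correct"], dtype=bool)
    levels = np.unique(soa)
    if levels.size < 2:
        raise ValueError("need at least 2 distinct SOA levels")
    n = np.array([np.sum(soa == s) for s in levels], dtype=float)
    k = np.array([np.sum(correct[soa == s]) for s in levels], dtype=float)

    fit = fit_psychometric(levels, n, k)
    threshold = fit.pop("threshold")
    flagged = (not fit["converged"]) or not (
        levels.min() / 2 <= threshold <= 2 * levels.max())
    return TaskScore(task="VDT", subject_id=subject_id, condition=condition,
                     session=session, value=threshold,
                     n_valid_trials=int(soa.size), flagged=bool(flagged),
                     fit_diagnostics=fit)


def mtt_score(trials: pd.DataFrame, group_values: np.ndarray,
              subject_id: str = "", condition: str = "",
              session: str = "") -> TaskScore:
    """Mean log on-path time, excluding trials > 3.5 group-SDs from the
    group mean log-time.

    ``group_values`` is the pooled vector of log-times across the whole
    group from which the outlier statistics are computed (single pass).
    """
    t = np.asarray(trials["on_path_time_s"], dtype=float)
    if np.any(t <= 0):
        raise ValueError("on-path times must be positive")
    log_t = np.log(t)
    group = np.asarray(group_values, dtype=float)
    mu, sd = group.mean(), group.std(ddof=1) if group.size > 1 else 0.0
    keep = np.abs(log_t - mu) <= MTT_OUTLIER_SD * sd if sd > 0 else np.ones_like(log_t, bool)
    if not keep.any():
        raise ValueError("all MTT trials removed as outliers")
    return TaskScore(task="MTT", subject_id=subject_id, condition=condition,
                     session=session, value=float(log_t[keep].mean()),
                     n_valid_trials=int(keep.sum()))


def overnight_gain(evening: TaskScore, morning: TaskScore) -> float:
    """Overnight performance gain: 100 x (evening - morning) / evening."""
    if evening.value == 0:
        raise ValueError("evening performance is zero; gain undefined")
    return 100.0 * (evening.value - morning.value) / evening.value


def score_sessions(sessions: list[BehaviouralSession]) -> pd.DataFrame:
    """Score every session and derive per-subject overnight gains.

    Returns a tidy frame with one row per (subject, condition, task):
    evening score, morning score, and overnight gain.
    """
    scores: dict[tuple, TaskScore] = {}
    mtt_group = np.concatenate([
        np.log(np.asarray(s.trials["on_path_time_s"], float))
        for s in sessions if s.task == "MTT"]) if any(
            s.task == "MTT" for s in sessions) else np.array([])
    for s in sessions:
        if s.task == "PVT":
            sc = pvt_score(s.trials, s.subject_id, s.condition, s.session)
        elif s.task == "VDT":
            sc = vdt_threshold(s.trials, s.subject_id, s.condition, s.session)
        else:
            sc = mtt_score(s.trials, mtt_group, s.subject_id, s.condition, s.session)
        scores[(s.task, s.subject_id, s.condition, s.session)] = sc

    rows = []
    for (task, sid, cond, sess), sc in scores.items():
        if sess != "pre":
            continue
        post = scores.get((task, sid, cond, "post"))
        if post is None:
            continue
        rows.append({"task": task, "subject_id": sid, "condition": cond,
                     "evening": sc.value, "morning": post.value,
                     "gain_pct": overnight_gain(sc, post),
                     "flagged": sc.flagged or post.flagged})
    return pd.DataFrame(rows)
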
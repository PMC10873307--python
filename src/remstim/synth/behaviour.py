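"""Synthetic behavioural datasets for the three tasks.

Each subject gets, per condition (CNT/STM) and session (pre/post), a trial
table matching the task protocols: PVT reaction times (shifted-lognormal,
plausible range), VDT letter/orientation judgements generated from a
cumulative-Gaussian psychometric curve over the task's SOA blocks, and MTT
on-path times (log-normal across six figures).

Condition effects are injected on the overnight-gain scale: subject-level
gains are drawn around a task baseline, STM nights receive the configured
differential gain, and the post-sleep performance parameter is set to
``evening * (1 - gain/100)`` — the quantity the scoring module's gain
formula recovers.
"""
from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.stats import norm

from ..types import BehaviouralSession

#: Differential overnight gain (STM - CNT, percentage points) per task.
DEFAULT_EFFECTS: dict[str, float] = {"PVT": 0.0, "VDT": 20.71, "MTT": -11.60}

#: Baseline (CNT) overnight gain per task, percentage points.
BASELINE_GAIN: dict[str, float] = {"PVT": 0.0, "VDT": 0.0, "MTT": 15.0}

#: SOA ladder of the texture-discrimination task, ms (trials per level below).
VDT_SOA_BLOCKS: tuple[int, ...] = (400, 300, 200, 160, 120, 100, 80, 60, 40)
VDT_TRIALS_PER_SOA = 50
VDT_GUESS = 0.5
VDT_LAPSE = 0.02
VDT_SLOPE_MS = 30.0

_SUBJECT_GAIN_SD = 10.0   # between-subject spread of overnight gain (%)
_NIGHT_GAIN_SD = 15.0     # residual night-to-night spread (%)


def _psychometric(soa: np.ndarray, mu: float, sigma: float,
                  gamma: float = VDT_GUESS, lam: float = VDT_LAPSE) -> np.ndarray:
    return gamma + (1 - gamma - lam) * norm.cdf((soa - mu) / sigma)


def mu_for_threshold(threshold_soa: float, sigma: float = VDT_SLOPE_MS,
                     gamma: float = VDT_GUESS, lam: float = VDT_LAPSE,
                     criterion: float = 0.8) -> float:
    """Location parameter placing the psychometric curve's criterion point
    at ``threshold_soa``."""
    return threshold_soa - sigma * norm.ppf((criterion - gamma) / (1 - gamma - lam))


def _pvt_trials(rng: np.random.Generator, mean_rt_ms: float, n: int = 100) -> pd.DataFrame:
    rt = 100.0 + (mean_rt_ms - 100.0) * np.exp(rng.normal(0, 0.12, n))
    rt = np.clip(rt, 102.0, 498.0)
    return pd.DataFrame({"rt_ms": rt})


def _vdt_trials(rng: np.random.Generator, threshold_soa_ms: float) -> pd.DataFrame:
    mu = mu_for_threshold(threshold_soa_ms)
    rows = []
    for soa in VDT_SOA_BLOCKS:
        p = _psychometric(np.array([float(soa)]), mu, VDT_SLOPE_MS)[0]
        orient = rng.random(VDT_TRIALS_PER_SOA) < p
        letter = rng.random(VDT_TRIALS_PER_SOA) < 0.95
        for o, l in zip(orient, letter):
            rows.append((soa, bool(l), bool(o)))
    return pd.DataFrame(rows, columns=["soa_ms", "letter_correct", "orientation_correct"])


def _mtt_trials(rng: np.random.Generator, mean_log_time: float, n_figures: int = 6
                ) -> pd.DataFrame:
    log_t = rng.normal(mean_log_time, 0.08, n_figures)
    return pd.DataFrame({"figure": np.arange(1, n_figures + 1),
                         "on_path_time_s": np.exp(log_t)})


def generate_behavioural_dataset(n_subjects: int = 20,
                                 effects: dict[str, float] | None = None,
                                 seed: int = 0) -> list[BehaviouralSession]:
    """Full two-condition, pre/post behavioural dataset for all three tasks."""
    if n_subjects < 2:
        raise ValueError("need at least 2 subjects")
    effects = DEFAULT_EFFECTS if effects is None else {**DEFAULT_EFFECTS, **effects}
    rng = np.random.default_rng(seed)

    sessions: list[BehaviouralSession] = []
    for i in range(n_subjects):
        sid = f"S{i + 1:02d}"
        evening = {
            "PVT": float(np.clip(rng.normal(300.0, 25.0), 220, 420)),
            "VDT": float(np.clip(rng.normal(150.0, 20.0), 90, 280)),
            "MTT": float(rng.normal(np.log(60.0), 0.2)),
        }
        subj_gain = {task: rng.normal(0, _SUBJECT_GAIN_SD) for task in evening}
        for condition in ("CNT", "STM"):
            for task, eve in evening.items():
                gain = (BASELINE_GAIN[task] + subj_gain[task]
                        + (effects[task] if condition == "STM" else 0.0)
                        + rng.normal(0, _NIGHT_GAIN_SD))
                if task == "MTT":
                    # the MTT performance value is a log-time; bound the gain
                    # so a single night cannot move it by more than a factor
                    # e^2.5 in time, which would be an implausible session
                    gain = float(np.clip(gain, -60.0, 60.0))
                morning = eve * (1.0 - gain / 100.0)
                for session, target in (("pre", eve), ("post", morning)):
                    if task == "PVT":
                        trials = _pvt_trials(rng, target)
                    elif task == "VDT":
                        trials = _vdt_trials(rng, max(target, 20.0))
                    else:
                        trials = _mtt_trials(rng, target)
                    sessions.append(BehaviouralSession(
                        task=task, subject_id=sid, condition=condition,
                        session=session, trials=trials))
    return sessions


def sessions_to_frame(sessions: list[BehaviouralSession]) -> pd.DataFrame:
    """Flatten sessions into one trial-level table (for TSV export)."""
    frames = []
    for s in sessions:
        df = s.trials.copy()
        df.insert(0, "session", s.session)
        df.insert(0, "condition", s.condition)
        df.insert(0, "subject_id", s.subject_id)
        df.insert(0, "task", s.task)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
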
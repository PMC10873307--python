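"""Behavioural analysis: task scores, overnight gains, paired condition
comparisons, and the multivariable gain models.

Scores the simulated cohort's trial tables (results/night/behaviour.tsv),
computes overnight gains per task, compares STM vs CNT with the
normality-gated paired test, and fits gain ~ condition + REM-stage time
models on synthetic stage covariates. Writes results/behaviour/.
"""
from pathlib import Path

import numpy as np
import pandas as pd

from remstim.behaviour import score_sessions
from remstim.stats_models import multivar_gain_model, paired_compare
from remstim.types import BehaviouralSession

ROOT = Path(__file__).resolve().parents[1] / "results"
NIGHT, OUT = ROOT / "night", ROOT / "behaviour"
OUT.mkdir(parents=True, exist_ok=True)
SEED = 1

df = pd.read_csv(NIGHT / "behaviour.tsv", sep="\t")
sessions = [BehaviouralSession(task=t, subject_id=s, condition=c, session=x,
                               trials=g.reset_index(drop=True))
            for (t, s, c, x), g in
            df.groupby(["task", "subject_id", "condition", "session"],
                       sort=False)]
scores = score_sessions(sessions)
scores.to_csv(OUT / "scores.tsv", sep="\t", index=False)

rng = np.random.default_rng(SEED)
comp_rows, model_rows = [], []
for task, g in scores.groupby("task"):
    wide = g.pivot(index="subject_id", columns="condition",
                   values="gain_pct").dropna()
    res = paired_compare(wide["STM"], wide["CNT"])
    diff = wide["STM"] - wide["CNT"]
    comp_rows.append({"task": task, "n": len(wide), "test": res.test,
                      "statistic": round(res.statistic, 3),
                      "p": res.p_value, "cohens_d": round(res.cohens_d, 3),
                      "mean_diff_pct": round(diff.mean(), 2)})
    # gain ~ condition + tonic-REM time, on synthetic stage covariates
    long = g.reset_index(drop=True)
    cond = (long["condition"] == "STM").astype(float).to_numpy()
    tonic_min = rng.uniform(20, 60, len(long))
    fit = multivar_gain_model(long["gain_pct"].to_numpy(), cond, tonic_min)
    model_rows.append({"task": task,
                       "b0": round(fit.coefficients[0], 2),
                       "b1_condition": round(fit.coefficients[1], 2),
                       "b2_stage": round(fit.coefficients[2], 3),
                       "p_condition": fit.p_values[1],
                       "r_squared": round(fit.r_squared, 3),
                       "f_p": fit.f_pvalue})

pd.DataFrame(comp_rows).to_csv(OUT / "condition_comparisons.tsv", sep="\t",
                               index=False)
pd.DataFrame(model_rows).to_csv(OUT / "gain_models.tsv", sep="\t", index=False)
print(pd.DataFrame(comp_rows).to_string(index=False))
print(pd.DataFrame(model_rows).to_string(index=False))
print(f"tables in {OUT}")
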
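"""Descriptive statistics for tidy calculation and cueing trial tables.

All operational-momentum quantities live on the log10 scale: a subject's
bias for an operation is the mean of log10(chosen) - log10(correct), and
the OM difference is addition bias minus subtraction bias (positive =
regular momentum, negative = inverse momentum).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

ARITHMETIC_TASKS = ("addition", "subtraction")
OUTCOMES = (8, 10, 19, 25)


def om_bias(trials: pd.DataFrame, *, include_memory: bool = False) -> pd.DataFrame:
    """Per-subject log10 response bias by operation, plus the OM difference.

    Returns one row per subject with columns ``group``, ``bias_addition``,
    ``bias_subtraction`` (and ``bias_memorization`` when requested) and
    ``om_difference = bias_addition - bias_subtraction``.  Subjects missing
    an arithmetic operation entirely are dropped with a warning.
    """
    tasks = ARITHMETIC_TASKS + (("memorization",) if include_memory else ())
    sub = trials[trials["task"].isin(tasks)].copy()
    if (sub["chosen"] <= 0).any() or (sub["correct"] <= 0).any():
        raise ValueError("chosen and correct values must be positive")
    sub["log_bias"] = np.log10(sub["chosen"].astype(float)) - np.log10(
        sub["correct"].astype(float)
    )
    wide = (
        sub.groupby(["subject_id", "group", "task"])["log_bias"]
        .mean()
        .unstack("task")
        .rename(columns=lambda t: f"bias_{t}")
        .reset_index()
    )
    incomplete = wide["bias_addition"].isna() | wide["bias_subtraction"].isna()
    if incomplete.any():
        dropped = wide.loc[incomplete, "subject_id"].tolist()
        logger.warning("dropping subjects without both operations: %s", dropped)
        wide = wide[~incomplete]
    wide = wide.copy()
    wide["om_difference"] = wide["bias_addition"] - wide["bias_subtraction"]
    return wide.reset_index(drop=True)


def cv_profile(trials: pd.DataFrame) -> pd.DataFrame:
    """Coefficient of variation of chosen values per operation x outcome.

    The SD is the across-trial sample SD pooled over subjects within each
    cell (per-subject CVs at 2-4 trials per cell are dominated by noise);
    CV = SD / mean.  Cells with fewer than two trials are returned with a
    missing CV.
    """
    sub = trials[trials["task"].isin(ARITHMETIC_TASKS + ("memorization",))]
    rows = []
    for (task, outcome), cell in sub.groupby(["task", "correct"]):
        chosen = cell["chosen"].astype(float)
        mean = chosen.mean()
        sd = chosen.std(ddof=1) if len(chosen) >= 2 else np.nan
        rows.append({
            "task": task, "outcome": int(outcome), "n_trials": len(chosen),
            "mean_chosen": mean, "sd_chosen": sd,
            "cv": sd / mean if np.isfinite(sd) and mean > 0 else np.nan,
        })
    return pd.DataFrame(rows).sort_values(["task", "outcome"]).reset_index(drop=True)


def rank_distribution(trials: pd.DataFrame) -> pd.DataFrame:
    """Choice-rank proportions per operation x range, arcsine-transformed.

    The rank of a choice is its 1-based position among the six sorted
    alternatives; proportions over ranks sum to 1 within each cell and are
    reported alongside arcsin(sqrt(p)).  Rows whose chosen value is not
    among the alternatives are rejected and counted in the log.
    """
    sub = trials[trials["task"].isin(ARITHMETIC_TASKS + ("memorization",))].copy()

    def rank_of(row) -> int:
        alts = sorted(int(a) for a in str(row["alternatives"]).split(";"))
        try:
            return alts.index(int(row["chosen"])) + 1
        except ValueError:
            return -1

    sub["rank"] = sub.apply(rank_of, axis=1)
    bad = int((sub["rank"] == -1).sum())
    if bad:
        logger.warning("rejected %d rows whose chosen value is not displayed", bad)
        sub = sub[sub["rank"] != -1]
    rows = []
    for (task, rf), cell in sub.groupby(["task", "range_flag"]):
        counts = cell["rank"].value_counts()
        total = len(cell)
        for rank in range(1, 7):
            p = counts.get(rank, 0) / total
            rows.append({
                "task": task, "range_flag": rf, "rank": rank,
                "proportion": p, "arcsine": float(np.arcsin(np.sqrt(p))),
            })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class RegressionResult:
    per_subject: pd.DataFrame  # subject_id, group, intercept, slope, n_points
    intercept_t: float
    intercept_p: float
    slope_t: float
    slope_p: float
    slope_null: float


def memory_regression(trials: pd.DataFrame, *, slope_null: float = 0.0) -> RegressionResult:
    """Per-subject OLS of chosen on shown numerosity for memory trials.

    Group-level one-sample t-tests ask whether intercepts differ from zero
    and slopes from ``slope_null`` (0 to test for any dependence on the
    shown value, 1 to test for deviation from perfect calibration).
    Subjects with fewer than two distinct shown numerosities are skipped.
    """
    mem = trials[trials["task"] == "memorization"]
    rows = []
    for (sid, group), cell in mem.groupby(["subject_id", "group"]):
        x = cell["correct"].astype(float).to_numpy()
        y = cell["chosen"].astype(float).to_numpy()
        if len(np.unique(x)) < 2:
            logger.warning("skipping %s: fewer than 2 distinct shown numerosities", sid)
            continue
        fit = stats.linregress(x, y)
        rows.append({
            "subject_id": sid, "group": group,
            "intercept": float(fit.intercept), "slope": float(fit.slope),
            "n_points": len(x),
        })
    per_subject = pd.DataFrame(rows)
    if len(per_subject) < 2:
        raise ValueError("need at least two subjects with memory regressions")
    t_a, p_a = stats.ttest_1samp(per_subject["intercept"], 0.0)
    t_b, p_b = stats.ttest_1samp(per_subject["slope"], slope_null)
    return RegressionResult(per_subject, float(t_a), float(p_a), float(t_b),
                            float(p_b), slope_null)


def cueing_effects(cueing_trials: pd.DataFrame) -> pd.DataFrame:
    """Per-subject orienting and reorienting effects on z-standardized RTs.

    Only correct responses enter.  Each subject's correct-trial RTs are
    z-scored (mean 0, SD 1 within subject; an all-equal RT vector maps to
    all zeros), then averaged by validity condition.  Orienting is
    neutral - valid (a benefit, typically positive); reorienting is
    neutral - invalid (a cost, typically negative).  Subjects missing any
    condition are excluded with a warning.
    """
    ok = cueing_trials[cueing_trials["response_correct"].astype(bool)].copy()
    rows = []
    for (sid, group), cell in ok.groupby(["subject_id", "group"]):
        rt = cell["rt_ms"].astype(float)
        sd = rt.std(ddof=0)
        z = (rt - rt.mean()) / sd if sd > 0 else rt * 0.0
        cell = cell.assign(z=z)
        means = cell.groupby("validity")["z"].mean()
        if not {"valid", "invalid", "neutral"} <= set(means.index):
            logger.warning("excluding %s: empty cueing condition", sid)
            continue
        rows.append({
            "subject_id": sid, "group": group,
            "z_valid": means["valid"], "z_neutral": means["neutral"],
            "z_invalid": means["invalid"],
            "orienting": means["neutral"] - means["valid"],
            "reorienting": means["neutral"] - means["invalid"],
            "n_correct": len(cell),
        })
    return pd.DataFrame(rows)


def correlate(x, y) -> tuple[float, float]:
    """Pearson correlation with two-sided p from the t transform.

    Returns ``(nan, nan)`` (with a warning) when either vector is constant,
    where the coefficient is undefined.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need at least 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        logger.warning("correlation undefined: zero variance input")
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)
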
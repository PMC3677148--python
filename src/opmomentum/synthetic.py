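"""Simulated child and adult cohorts for the approximate-calculation tasks.

The generator realises the standard approximate-number-system account: a
subject's internal estimate of a trial's correct outcome is log-normally
distributed around it (Weber's law; the log-scale SD ``w`` is constant
across magnitudes), shifted by an operation-specific multiplicative bias.
The chosen alternative is the displayed value nearest the estimate on the
log scale.  Cueing reaction times are log-normal with additive
orienting/reorienting condition effects after exponentiation.

None of the subject-level parameters are estimates of any real cohort;
they are generative stand-ins whose defaults produce the qualitative
pattern of interest (regular operational momentum in adults, inverse in
children, children noisier than adults, OM correlated with reorienting).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .design import (
    CueingSchedule,
    ProblemSpec,
    ResponseSet,
    SessionSchedule,
    build_cueing_schedule,
    build_session_schedule,
)

LN10 = math.log(10.0)

TRIAL_COLUMNS = [
    "subject_id", "group", "task", "operand1", "operand2", "correct",
    "range_flag", "area_mode", "alternatives", "chosen", "rt_ms",
    "response_correct",
]
CUEING_COLUMNS = [
    "subject_id", "group", "task", "validity", "soa_ms", "target_side",
    "rt_ms", "response_correct",
]


@dataclass(frozen=True)
class SubjectParams:
    """Generative parameters of one simulated subject.

    Biases are in log10 units (the scale of the OM statistic); ``weber``
    is the natural-log SD of the magnitude estimate.  RT parameters are in
    log-ms (``rt_base``, ``rt_noise``) and ms (``rt_orient``,
    ``rt_reorient`` — the latter is the *cost* added to invalid trials).
    """

    subject_id: str
    group: str  # "child" | "adult"
    weber: float
    bias_add: float
    bias_sub: float
    bias_mem: float
    lapse: float
    rt_base: float
    rt_orient: float
    rt_reorient: float
    rt_noise: float
    error_rate: float

    def __post_init__(self) -> None:
        if self.weber <= 0:
            raise ValueError("weber fraction must be positive")
        if not 0 <= self.lapse < 1:
            raise ValueError("lapse must be in [0, 1)")
        if not 0 <= self.error_rate < 1:
            raise ValueError("error_rate must be in [0, 1)")

    def bias_for(self, task: str) -> float:
        return {"addition": self.bias_add, "subtraction": self.bias_sub,
                "memorization": self.bias_mem}[task]


@dataclass(frozen=True)
class GroupParams:
    """Population distribution from which subjects of one group are drawn.

    ``rho_om_reorient`` is the correlation between a subject's OM parameter
    (bias_add - bias_sub) and the rt_reorient cost parameter.  Because the
    measured reorienting effect is neutral - invalid (approximately minus
    the cost), a *negative* rho here yields the positive OM x reorienting
    correlation reported for children.
    """

    group: str
    bias_add_mean: float
    bias_sub_mean: float
    bias_mem_mean: float
    bias_sd: float  # between-subject SD of each operation bias
    weber_mean: float
    weber_sd: float
    lapse: float
    rt_base_mean: float = math.log(700.0)
    rt_base_sd: float = 0.15
    rt_orient_mean: float = 30.0
    rt_orient_sd: float = 12.0
    rt_reorient_mean: float = 60.0
    rt_reorient_sd: float = 25.0
    rt_noise: float = 0.2
    error_rate: float = 0.02
    rho_om_reorient: float = 0.0

    def __post_init__(self) -> None:
        if self.bias_sd < 0 or self.weber_sd < 0:
            raise ValueError("population SDs must be non-negative")
        if abs(self.rho_om_reorient) > 1:
            raise ValueError("|rho_om_reorient| must be <= 1")


#: Default study conditions: 32 + 32 subjects with adults showing regular
#: operational momentum (overestimate addition, underestimate subtraction),
#: children the inverse pattern, and children more variable throughout.
ADULT_DEFAULTS = GroupParams(
    group="adult",
    bias_add_mean=0.02, bias_sub_mean=-0.05, bias_mem_mean=0.0,
    bias_sd=0.05, weber_mean=0.15, weber_sd=0.03, lapse=0.01,
)
CHILD_DEFAULTS = GroupParams(
    group="child",
    bias_add_mean=0.0, bias_sub_mean=0.03, bias_mem_mean=0.01,
    bias_sd=0.08, weber_mean=0.25, weber_sd=0.05, lapse=0.05,
    rho_om_reorient=-0.6,
)
DEFAULT_N_PER_GROUP = 32


def simulate_choice(
    problem: ProblemSpec,
    response_set: "ResponseSet | Sequence[int]",
    params: SubjectParams,
    rng: np.random.Generator,
) -> int:
    """One trial's chosen alternative under the log-normal estimate model.

    With probability ``lapse`` the choice is uniform over the displayed
    alternatives; otherwise the internal estimate
    ``X = exp(ln(correct) + bias*ln10 + w*Z)`` is mapped to the nearest
    alternative on the log scale (ties to the smaller value).  A plain
    sequence of alternatives may stand in for a :class:`ResponseSet`,
    e.g. a dense grid for unconstrained-choice studies.
    """
    alts = (
        response_set.alternatives
        if isinstance(response_set, ResponseSet)
        else tuple(response_set)
    )
    if params.lapse > 0 and rng.random() < params.lapse:
        return int(alts[rng.integers(len(alts))])
    log_x = math.log(problem.correct) + params.bias_for(problem.operation) * LN10
    if params.weber > 0:
        log_x += params.weber * rng.standard_normal()
    dists = [abs(math.log(a) - log_x) for a in alts]
    best = min(range(len(alts)), key=lambda i: (dists[i], alts[i]))
    return int(alts[best])


def simulate_session(
    params: SubjectParams,
    schedule: SessionSchedule,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the 44 test trials of one calculation session."""
    rows = []
    for trial in schedule.test.trials:
        chosen = simulate_choice(trial.problem, trial.response_set, params, rng)
        rt = math.exp(params.rt_base + params.rt_noise * rng.standard_normal()) * 4.0
        rows.append({
            "subject_id": params.subject_id,
            "group": params.group,
            "task": trial.problem.operation,
            "operand1": trial.problem.operand1,
            "operand2": trial.problem.operand2,
            "correct": trial.problem.correct,
            "range_flag": trial.response_set.range_flag,
            "area_mode": trial.area_mode,
            "alternatives": ";".join(str(a) for a in trial.response_set.alternatives),
            "chosen": chosen,
            "rt_ms": round(rt, 3),
            "response_correct": chosen == trial.problem.correct,
        })
    return pd.DataFrame(rows, columns=TRIAL_COLUMNS)


def simulate_cueing(
    params: SubjectParams,
    schedule: CueingSchedule,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate the 60 cueing test trials of one subject.

    RT = exp(rt_base + rt_noise*Z), minus rt_orient on valid trials and
    plus the rt_reorient cost on invalid trials; the response side is wrong
    with probability ``error_rate``.
    """
    rows = []
    for trial in schedule.test:
        rt = math.exp(params.rt_base + params.rt_noise * rng.standard_normal())
        if trial.validity == "valid":
            rt -= params.rt_orient
        elif trial.validity == "invalid":
            rt += params.rt_reorient
        rt = max(rt, 1.0)
        correct = rng.random() >= params.error_rate
        rows.append({
            "subject_id": params.subject_id,
            "group": params.group,
            "task": "cueing",
            "validity": trial.validity,
            "soa_ms": trial.soa_ms,
            "target_side": trial.target_side,
            "rt_ms": round(float(rt), 3),
            "response_correct": bool(correct),
        })
    return pd.DataFrame(rows, columns=CUEING_COLUMNS)


def draw_subject(
    gp: GroupParams, subject_id: str, rng: np.random.Generator
) -> SubjectParams:
    """Draw one subject from the group population.

    The operation biases are built from an independent mean-bias component
    and an OM component (bias_add - bias_sub); the OM component is drawn
    jointly with rt_reorient at correlation ``rho_om_reorient``.  This
    parameterisation keeps Var(bias_add) = Var(bias_sub) = bias_sd**2.
    """
    om_mean = gp.bias_add_mean - gp.bias_sub_mean
    om_sd = gp.bias_sd * math.sqrt(2.0)
    z1, z2 = rng.standard_normal(2)
    om = om_mean + om_sd * z1
    rho = gp.rho_om_reorient
    reorient = gp.rt_reorient_mean + gp.rt_reorient_sd * (
        rho * z1 + math.sqrt(max(1.0 - rho * rho, 0.0)) * z2
    )
    mid = (gp.bias_add_mean + gp.bias_sub_mean) / 2.0
    mid += (gp.bias_sd / math.sqrt(2.0)) * rng.standard_normal()
    return SubjectParams(
        subject_id=subject_id,
        group=gp.group,
        weber=max(gp.weber_mean + gp.weber_sd * rng.standard_normal(), 0.01),
        bias_add=mid + om / 2.0,
        bias_sub=mid - om / 2.0,
        bias_mem=gp.bias_mem_mean + gp.bias_sd * rng.standard_normal(),
        lapse=gp.lapse,
        rt_base=gp.rt_base_mean + gp.rt_base_sd * rng.standard_normal(),
        rt_orient=gp.rt_orient_mean + gp.rt_orient_sd * rng.standard_normal(),
        rt_reorient=float(reorient),
        rt_noise=gp.rt_noise,
        error_rate=gp.error_rate,
    )


def simulate_cohort(
    child_params: GroupParams = CHILD_DEFAULTS,
    adult_params: GroupParams = ADULT_DEFAULTS,
    n_per_group: int = DEFAULT_N_PER_GROUP,
    seed: int = 0,
    *,
    cueing_groups: tuple[str, ...] = ("child",),
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Simulate a full two-group cohort.

    Returns ``(trials, cueing, truth)``: the tidy calculation-trial table,
    the cueing-trial table (by default children only, mirroring the study
    design), and the ground-truth subject parameters for recovery checks.
    Fully reproducible from ``seed``; each subject runs a freshly seeded
    session schedule so trial orders differ between subjects.
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    root = np.random.SeedSequence(seed)
    trial_frames, cueing_frames, truth_rows = [], [], []
    for gp, prefix in ((adult_params, "adult"), (child_params, "child")):
        for i in range(n_per_group):
            ss = root.spawn(1)[0]
            rng = np.random.default_rng(ss)
            sid = f"{prefix}{i + 1:02d}"
            subject = draw_subject(gp, sid, rng)
            sched_seed = int(rng.integers(2**31 - 1))
            schedule = build_session_schedule(sched_seed)
            trial_frames.append(simulate_session(subject, schedule, rng))
            if gp.group in cueing_groups:
                cue_sched = build_cueing_schedule(int(rng.integers(2**31 - 1)))
                cueing_frames.append(simulate_cueing(subject, cue_sched, rng))
            truth_rows.append({
                "subject_id": sid, "group": gp.group,
                "weber": subject.weber, "bias_add": subject.bias_add,
                "bias_sub": subject.bias_sub, "bias_mem": subject.bias_mem,
                "lapse": subject.lapse, "rt_base": subject.rt_base,
                "rt_orient": subject.rt_orient,
                "rt_reorient": subject.rt_reorient,
                "rt_noise": subject.rt_noise, "error_rate": subject.error_rate,
            })
    trials = pd.concat(trial_frames, ignore_index=True)
    cueing = (
        pd.concat(cueing_frames, ignore_index=True)
        if cueing_frames else pd.DataFrame(columns=CUEING_COLUMNS)
    )
    truth = pd.DataFrame(truth_rows)
    return trials, cueing, truth


def simulate_bias_scores(
    mu: np.ndarray, sigma: np.ndarray, n: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw n per-subject (addition, subtraction) score pairs ~ N(mu, sigma).

    Direct score-level simulation used for sampler recovery studies; raises
    if ``sigma`` is not positive-definite.
    """
    mu = np.asarray(mu, dtype=float)
    sigma = np.asarray(sigma, dtype=float)
    try:
        chol = np.linalg.cholesky(sigma)
    except np.linalg.LinAlgError as exc:
        raise ValueError("score covariance must be positive-definite") from exc
    return mu + rng.standard_normal((n, 2)) @ chol.T
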
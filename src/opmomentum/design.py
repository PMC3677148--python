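"""Stimulus construction for the non-symbolic calculation and cueing tasks.

Every problem is an operand pair whose outcome is embedded in a geometric
series of nine candidate results spanning half to double the correct value,
``round(c * 2**(i/4))`` for i = -4..+4.  Six of the nine are shown on a
given trial: the lower six ("low" range, correct value fifth-smallest) or
the upper six ("high" range, correct value second-smallest).  Dot arrays
realise each numerosity with either total area or individual dot size held
constant, so that neither cue predicts number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

Operation = Literal["addition", "subtraction", "memorization"]
RangeFlag = Literal["low", "high"]
AreaMode = Literal["fixed_total_area", "fixed_dot_size"]

#: Operand pairs of the calculation session.  Addition and subtraction
#: cover the same outcomes {8, 10, 19, 25}; memorization problems present a
#: single numerosity (second operand zero).
ADDITION_OPERANDS = ((6, 2), (6, 4), (14, 5), (14, 11))
SUBTRACTION_OPERANDS = ((16, 8), (16, 6), (32, 13), (32, 7))
MEMORY_OPERANDS = ((6, 0), (19, 0), (25, 0))

TEST_RESPONSE_LIMIT_S = 20.0
N_TRAINING_TRIALS = 8


def _round_half_away_from_zero(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class DeviantSeries:
    """Nine candidate outcomes, geometrically spaced from c/2 to 2c."""

    correct: int
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.values) != 9:
            raise ValueError(f"series must have 9 values, got {len(self.values)}")
        if self.values[4] != self.correct:
            raise ValueError("middle series value must equal the correct result")
        if any(b < a for a, b in zip(self.values, self.values[1:])):
            raise ValueError("series values must be non-decreasing")


@dataclass(frozen=True)
class ProblemSpec:
    operation: Operation
    operand1: int
    operand2: int
    correct: int
    series: DeviantSeries

    def __post_init__(self) -> None:
        expected = {
            "addition": self.operand1 + self.operand2,
            "subtraction": self.operand1 - self.operand2,
            "memorization": self.operand1,
        }[self.operation]
        if self.correct != expected:
            raise ValueError(
                f"{self.operation} {self.operand1},{self.operand2} should give "
                f"{expected}, got correct={self.correct}"
            )
        if self.operation == "memorization" and self.operand2 != 0:
            raise ValueError("memorization problems must have a zero second operand")


@dataclass(frozen=True)
class ResponseSet:
    """The six on-screen alternatives and the rank of the correct one."""

    range_flag: RangeFlag
    alternatives: tuple[int, ...]
    correct_rank: int  # 1-based rank of the correct value among the six

    def __post_init__(self) -> None:
        if len(self.alternatives) != 6:
            raise ValueError("exactly six alternatives are displayed")
        if self.correct_rank not in (2, 5):
            raise ValueError("correct value must be second or fifth smallest")


@dataclass(frozen=True)
class DotArraySpec:
    n: int
    mode: AreaMode
    field_size: tuple[float, float]
    dots: tuple[tuple[float, float, float], ...]  # (x, y, radius)

    @property
    def total_area(self) -> float:
        return float(sum(math.pi * r * r for _, _, r in self.dots))


@dataclass(frozen=True)
class ScheduledTrial:
    problem: ProblemSpec
    response_set: ResponseSet
    area_mode: AreaMode
    slot_permutation: tuple[int, ...]  # alternative index -> screen slot


@dataclass(frozen=True)
class TrialSchedule:
    phase: Literal["training", "test"]
    trials: tuple[ScheduledTrial, ...]
    response_limit_s: float | None


@dataclass(frozen=True)
class SessionSchedule:
    training: TrialSchedule
    test: TrialSchedule


@dataclass(frozen=True)
class CueingTrial:
    cue: Literal["left", "right", "neutral"]
    target_side: Literal["left", "right"]
    soa_ms: int
    validity: Literal["valid", "invalid", "neutral"]


@dataclass(frozen=True)
class CueingSchedule:
    training: tuple[CueingTrial, ...]
    test: tuple[CueingTrial, ...]


def deviant_series(correct: int) -> DeviantSeries:
    """Build the raw nine-value series round(c * 2**(i/4)), i = -4..+4.

    Half-integer products round away from zero (12.5 -> 13).  Duplicates
    arising from rounding (only for c = 6 among the session's outcomes) are
    NOT resolved here; see :func:`resolve_duplicates`.
    """
    if not isinstance(correct, (int, np.integer)) or isinstance(correct, bool):
        raise TypeError(f"correct result must be an integer, got {correct!r}")
    if correct < 2:
        raise ValueError(f"correct result must be >= 2, got {correct}")
    values = tuple(
        _round_half_away_from_zero(correct * 2.0 ** (i / 4.0)) for i in range(-4, 5)
    )
    return DeviantSeries(correct=int(correct), values=values)


def resolve_duplicates(deviants: Sequence[int]) -> tuple[int, ...]:
    """Make a sorted deviant list distinct by decrementing smallest duplicates.

    While any value occurs more than once, one occurrence of the smallest
    duplicated value is decremented by 1 and the list re-scanned, e.g.
    [3,4,4,5,7,8,10,12] -> [2,3,4,5,7,8,10,12].
    """
    vals = list(deviants)
    if any(b < a for a, b in zip(vals, vals[1:])):
        raise ValueError("deviant list must be sorted non-decreasing")
    while True:
        dup = None
        for i in range(len(vals) - 1):
            if vals[i] == vals[i + 1]:
                dup = i
                break
        if dup is None:
            return tuple(vals)
        vals[dup] -= 1
        if vals[dup] < 1:
            raise ValueError("duplicate resolution would produce a value below 1")
        vals.sort()


def select_range(series: DeviantSeries, range_flag: RangeFlag) -> ResponseSet:
    """Pick the six displayed alternatives for one trial.

    Low range shows series positions 1-6 (correct fifth-smallest); high
    range shows positions 4-9 (correct second-smallest).  The two ranges
    share the three middle series values.
    """
    if len(set(series.values)) != 9:
        raise ValueError("series values must be distinct (resolve duplicates first)")
    if range_flag == "low":
        return ResponseSet("low", series.values[0:6], correct_rank=5)
    if range_flag == "high":
        return ResponseSet("high", series.values[3:9], correct_rank=2)
    raise ValueError(f"unknown range flag {range_flag!r}")


def _problem(operation: Operation, op1: int, op2: int) -> ProblemSpec:
    correct = op1 + op2 if operation == "addition" else (op1 - op2 if operation == "subtraction" else op1)
    series = deviant_series(correct)
    deviants = series.values[:4] + series.values[5:]
    if len(set(deviants)) < 8:
        deviants = resolve_duplicates(deviants)
        values = tuple(sorted(deviants + (correct,)))
        series = DeviantSeries(correct=correct, values=values)
    return ProblemSpec(operation, op1, op2, correct, series)


def build_problem_table() -> tuple[ProblemSpec, ...]:
    """The 11 problems of the session: 4 addition, 4 subtraction, 3 memory."""
    problems = [_problem("addition", a, b) for a, b in ADDITION_OPERANDS]
    problems += [_problem("subtraction", a, b) for a, b in SUBTRACTION_OPERANDS]
    problems += [_problem("memorization", a, b) for a, b in MEMORY_OPERANDS]
    return tuple(problems)


def build_session_schedule(seed: int) -> SessionSchedule:
    """Reproducible 44-trial test schedule plus 8 training trials.

    Each of the 8 arithmetic problems appears 4 times, crossing range
    {low, high} with area-control mode; each memory problem appears 4 times
    the same way (16 + 16 + 12 = 44).  Trial order and the assignment of
    the six alternatives to screen slots are drawn from ``seed``.
    """
    rng = np.random.default_rng(seed)
    problems = build_problem_table()

    def make_trial(problem: ProblemSpec, rf: RangeFlag, mode: AreaMode) -> ScheduledTrial:
        return ScheduledTrial(
            problem=problem,
            response_set=select_range(problem.series, rf),
            area_mode=mode,
            slot_permutation=tuple(int(i) for i in rng.permutation(6)),
        )

    combos = [
        (problem, rf, mode)
        for problem in problems
        for rf in ("low", "high")
        for mode in ("fixed_total_area", "fixed_dot_size")
    ]
    order = rng.permutation(len(combos))
    test_trials = tuple(make_trial(*combos[i]) for i in order)

    train_idx = rng.choice(len(combos), size=N_TRAINING_TRIALS, replace=False)
    training_trials = tuple(make_trial(*combos[i]) for i in train_idx)

    return SessionSchedule(
        training=TrialSchedule("training", training_trials, response_limit_s=None),
        test=TrialSchedule("test", test_trials, response_limit_s=TEST_RESPONSE_LIMIT_S),
    )


def build_cueing_schedule(seed: int) -> CueingSchedule:
    """Reproducible spatial-cueing schedule: 40 valid / 10 invalid / 10
    neutral test trials, target sides 50/50 within each validity class,
    SOAs of 200 and 800 ms balanced, preceded by 8 training trials."""
    rng = np.random.default_rng(seed)

    def cue_for(validity: str, side: str) -> str:
        if validity == "neutral":
            return "neutral"
        if validity == "valid":
            return side
        return "right" if side == "left" else "left"

    trials: list[CueingTrial] = []
    # 40 valid: fully crossed side x SOA, 10 each.
    for side in ("left", "right"):
        for soa in (200, 800):
            trials += [CueingTrial(cue_for("valid", side), side, soa, "valid")] * 10
    # 10 invalid and 10 neutral: sides 5/5 and SOAs 5/5; the 2x2 cell counts
    # (3,2,2,3) keep both margins balanced since 10 is not divisible by 4.
    for validity in ("invalid", "neutral"):
        counts = {("left", 200): 3, ("left", 800): 2, ("right", 200): 2, ("right", 800): 3}
        for (side, soa), c in counts.items():
            trials += [CueingTrial(cue_for(validity, side), side, soa, validity)] * c
    order = rng.permutation(len(trials))
    test = tuple(trials[i] for i in order)
    train_idx = rng.choice(len(trials), size=N_TRAINING_TRIALS, replace=False)
    training = tuple(trials[i] for i in train_idx)
    return CueingSchedule(training=training, test=test)


def generate_dot_array(
    n: int,
    mode: AreaMode,
    seed: int,
    *,
    field_size: tuple[float, float] = (400.0, 400.0),
    total_area: float = 12000.0,
    dot_radius: float = 7.0,
    min_gap: float = 2.0,
    max_attempts: int = 20000,
) -> DotArraySpec:
    """Place ``n`` non-overlapping dots by uniform rejection sampling.

    In ``fixed_total_area`` mode every dot gets radius sqrt(A/(n*pi)) so the
    summed area equals ``total_area`` for any n; in ``fixed_dot_size`` mode
    every radius is ``dot_radius``.  Coordinates are abstract pixels.
    """
    if n < 1:
        raise ValueError("need at least one dot")
    if mode == "fixed_total_area":
        radius = math.sqrt(total_area / (n * math.pi))
    elif mode == "fixed_dot_size":
        radius = float(dot_radius)
    else:
        raise ValueError(f"unknown area mode {mode!r}")
    w, h = field_size
    if 2 * radius >= min(w, h):
        raise ValueError("field too small for the requested dots; enlarge field_size")
    rng = np.random.default_rng(seed)
    dots: list[tuple[float, float, float]] = []
    attempts = 0
    while len(dots) < n:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n} dots after {max_attempts} attempts; "
                "use a larger field_size"
            )
        attempts += 1
        x = rng.uniform(radius, w - radius)
        y = rng.uniform(radius, h - radius)
        ok = all(
            math.hypot(x - ox, y - oy) >= radius + orad + min_gap
            for ox, oy, orad in dots
        )
        if ok:
            dots.append((float(x), float(y), radius))
    return DotArraySpec(n=n, mode=mode, field_size=(float(w), float(h)), dots=tuple(dots))
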
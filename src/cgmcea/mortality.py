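"""Mortality schedules: baseline all-cause death probabilities by age plus
state-specific hazard multipliers.

The published model drew its all-cause mortality from CDC life tables
(averaged over race and sex) and its state-specific increased risks from the
ETDRS follow-up; those tables live in a supplementary appendix that is not
reproduced here. This module therefore provides a synthetic stand-in: a
Gompertz baseline calibrated so the SMBG cohort's life expectancy from age 40
matches the model's 73-year anchor, with placeholder multipliers that can be
overridden, and a CSV loader for real schedules when available.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .states import N_STATES, State

logger = logging.getLogger(__name__)

__all__ = [
    "MortalitySchedule",
    "ScheduleValidationError",
    "CalibrationError",
    "DEFAULT_MULTIPLIERS",
    "DEFAULT_GOMPERTZ_B",
    "generate_schedule",
    "calibrate_baseline",
    "load_schedule",
    "save_schedule",
]

#: Synthetic placeholder hazard multipliers (NOT published values): chosen to
#: be ordered plausibly (renal and macrovascular disease deadliest), override
#: via config or a schedule CSV when better estimates are available.
DEFAULT_MULTIPLIERS: dict[State, float] = {
    State.NO_COMPLICATIONS: 1.0,
    State.RETINOPATHY: 1.2,
    State.NEUROPATHY: 1.5,
    State.NEPHROPATHY: 2.0,
    State.CHD: 2.5,
    State.BLINDNESS: 1.3,
    State.ESRD: 4.0,
    State.LEA: 3.0,
}

#: Gompertz slope (per year of age) for the synthetic baseline.
DEFAULT_GOMPERTZ_B = 0.085

#: Composite states take the maximum of their components' multipliers unless
#: given explicitly (conservative: avoids double-counting shared risk).
COMPOSITE_COMPONENTS: dict[State, tuple[State, State]] = {
    State.NEPHROPATHY_CHD: (State.NEPHROPATHY, State.CHD),
    State.NEUROPATHY_CHD: (State.NEUROPATHY, State.CHD),
    State.RETINOPATHY_CHD: (State.RETINOPATHY, State.CHD),
    State.NEUROPATHY_NEPHROPATHY: (State.NEUROPATHY, State.NEPHROPATHY),
}

#: Column names used in the mortality CSV format, one per living state.
_CSV_CATEGORY = {
    State.NO_COMPLICATIONS: "NoComplications",
    State.RETINOPATHY: "Retinopathy",
    State.NEPHROPATHY: "Nephropathy",
    State.NEUROPATHY: "Neuropathy",
    State.CHD: "CHD",
    State.BLINDNESS: "Blindness",
    State.ESRD: "ESRD",
    State.LEA: "LEA",
    State.NEPHROPATHY_CHD: "NephropathyCHD",
    State.NEUROPATHY_CHD: "NeuropathyCHD",
    State.RETINOPATHY_CHD: "RetinopathyCHD",
    State.NEUROPATHY_NEPHROPATHY: "NeuropathyNephropathy",
}
_CATEGORY_STATE = {v: k for k, v in _CSV_CATEGORY.items()}


class ScheduleValidationError(ValueError):
    pass


class CalibrationError(RuntimeError):
    pass


def _fill_composites(multipliers: dict[State, float]) -> dict[State, float]:
    filled = dict(multipliers)
    for comp, (a, b) in COMPOSITE_COMPONENTS.items():
        if comp not in filled:
            filled[comp] = max(filled[a], filled[b])
            logger.info(
                "mortality multiplier for %s filled as max(%s, %s) = %.3g",
                comp.name, a.name, b.name, filled[comp],
            )
    return filled


@dataclass(frozen=True)
class MortalitySchedule:
    """Per-age baseline annual death probability plus per-state multipliers."""

    ages: np.ndarray
    baseline_q: np.ndarray
    multipliers: dict[State, float] = field(default_factory=dict)
    gompertz_a: float | None = None  # set when generated, for calibration
    gompertz_b: float | None = None

    def __post_init__(self) -> None:
        ages = np.asarray(self.ages, dtype=int)
        q = np.asarray(self.baseline_q, dtype=float)
        object.__setattr__(self, "ages", ages)
        object.__setattr__(self, "baseline_q", q)
        object.__setattr__(self, "multipliers", _fill_composites(dict(self.multipliers)))
        self.validate()

    def validate(self) -> None:
        if self.ages.size != self.baseline_q.size:
            raise ScheduleValidationError("ages and baseline_q differ in length")
        if self.ages.size == 0:
            raise ScheduleValidationError("empty schedule")
        if np.any(np.diff(self.ages) != 1):
            raise ScheduleValidationError("ages must be contiguous integers")
        bad = np.where((self.baseline_q < 0) | (self.baseline_q >= 1))[0]
        if bad.size:
            raise ScheduleValidationError(
                f"baseline_q = {self.baseline_q[bad[0]]} outside [0, 1) at age {self.ages[bad[0]]}"
            )
        missing = [s for s in State if s is not State.DEATH and s not in self.multipliers]
        if missing:
            raise ScheduleValidationError(f"missing multipliers for {missing}")
        for s, m in self.multipliers.items():
            if m < 1.0:
                raise ScheduleValidationError(
                    f"multiplier for {_CSV_CATEGORY[s]} is {m} < 1"
                )

    def q_for(self, ages: np.ndarray) -> np.ndarray:
        """Baseline death probabilities at the requested integer ages."""
        ages = np.asarray(ages, dtype=int)
        lo, hi = int(self.ages[0]), int(self.ages[-1])
        if np.any(ages < lo) or np.any(ages > hi):
            raise ScheduleValidationError(
                f"requested ages outside schedule range [{lo}, {hi}]"
            )
        return self.baseline_q[ages - lo]

    def multiplier_vector(self) -> np.ndarray:
        """Multipliers in state order; the death entry is 0."""
        v = np.zeros(N_STATES)
        for s in State:
            if s is not State.DEATH:
                v[s] = self.multipliers[s]
        return v

    def scaled(self, factor: float) -> "MortalitySchedule":
        """Schedule with baseline probabilities scaled (clipped below 1)."""
        return MortalitySchedule(
            self.ages,
            np.clip(self.baseline_q * factor, 0.0, 0.999),
            self.multipliers,
        )


def gompertz_q(age: np.ndarray, a: float, b: float) -> np.ndarray:
    """Annual death probability 1 - exp(-a e^(b age)), clipped to [0, 0.999]."""
    q = 1.0 - np.exp(-a * np.exp(b * np.asarray(age, dtype=float)))
    return np.clip(q, 0.0, 0.999)


def generate_schedule(
    gompertz_a: float,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    multipliers: dict[State, float] | None = None,
    age_range: tuple[int, int] = (40, 73),
) -> MortalitySchedule:
    """Synthetic schedule with a Gompertz baseline over [age_lo, age_hi]."""
    if gompertz_a <= 0 or gompertz_b <= 0:
        raise ValueError("Gompertz parameters must be positive")
    ages = np.arange(age_range[0], age_range[1] + 1)
    mult = dict(DEFAULT_MULTIPLIERS) if multipliers is None else dict(multipliers)
    return MortalitySchedule(
        ages, gompertz_q(ages, gompertz_a, gompertz_b), mult,
        gompertz_a=gompertz_a, gompertz_b=gompertz_b,
    )


def calibrate_baseline(
    target_life_expectancy: float,
    multipliers: dict[State, float] | None = None,
    params=None,
    gompertz_b: float = DEFAULT_GOMPERTZ_B,
    max_age: int = 115,
    tol: float = 0.05,
) -> MortalitySchedule:
    """Scale the Gompertz level so the SMBG cohort hits a target life expectancy.

    Bisection on log(a); deterministic given the slope and multipliers. The
    returned schedule spans start_age..max_age so downstream runs (including
    extended-horizon life-expectancy checks) never fall off its edge.
    """
    from .engine import Arm, life_expectancy
    from .parameters import build_parameters

    if params is None:
        params = build_parameters()

    age_range = (params.start_age, max_age)

    def le(log_a: float) -> float:
        sched = generate_schedule(math.exp(log_a), gompertz_b, multipliers, age_range)
        return life_expectancy(params, sched, Arm.SMBG)

    lo, hi = math.log(1e-12), math.log(0.5)
    le_lo, le_hi = le(lo), le(hi)
    if not (le_hi <= target_life_expectancy <= le_lo):
        raise CalibrationError(
            f"target {target_life_expectancy} outside achievable bracket "
            f"[{le_hi:.2f}, {le_lo:.2f}]"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        le_mid = le(mid)
        if abs(le_mid - target_life_expectancy) <= tol:
            return generate_schedule(math.exp(mid), gompertz_b, multipliers, age_range)
        if le_mid > target_life_expectancy:
            lo = mid  # mortality too low -> raise a
        else:
            hi = mid
    raise CalibrationError("bisection failed to converge")  # pragma: no cover


def load_schedule(path) -> MortalitySchedule:
    """Read a mortality CSV: columns age, baseline_q, one per state category.

    Multiplier columns must be constant across ages (the model uses scalar
    hazard multipliers); missing composite columns are filled by the
    max-of-components rule with a logged notice.
    """
    df = pd.read_csv(path)
    for col in ("age", "baseline_q"):
        if col not in df.columns:
            raise ScheduleValidationError(f"missing required column '{col}'")
    ages = df["age"].to_numpy(dtype=int)
    q = df["baseline_q"].to_numpy(dtype=float)
    bad = np.where((q < 0) | (q >= 1))[0]
    if bad.size:
        raise ScheduleValidationError(
            f"baseline_q = {q[bad[0]]} outside [0, 1) at age {ages[bad[0]]}"
        )
    multipliers: dict[State, float] = {}
    for col in df.columns:
        if col in ("age", "baseline_q"):
            continue
        if col not in _CATEGORY_STATE:
            raise ScheduleValidationError(f"unknown mortality category column '{col}'")
        vals = df[col].to_numpy(dtype=float)
        if np.ptp(vals) != 0:
            raise ScheduleValidationError(f"multiplier column '{col}' varies by age")
        multipliers[_CATEGORY_STATE[col]] = float(vals[0])
    return MortalitySchedule(ages, q, multipliers)


def save_schedule(schedule: MortalitySchedule, path) -> None:
    """Write a schedule in the CSV format accepted by :func:`load_schedule`."""
    data = {"age": schedule.ages, "baseline_q": schedule.baseline_q}
    for s, name in _CSV_CATEGORY.items():
        data[name] = np.full(schedule.ages.size, schedule.multipliers[s])
    pd.DataFrame(data).to_csv(path, index=False)
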
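"""Deterministic two-arm Markov cohort engine.

The model follows a closed cohort of adults with type 1 diabetes (start age
40, 20 years since diagnosis) through 13 health states over annual cycles,
comparing self-monitoring of blood glucose (SMBG) against continuous glucose
monitoring (CGM) added to SMBG. CGM acts purely through relative risk
reductions on the incidence of retinopathy, nephropathy, neuropathy and CHD;
it never changes mortality directly.

Reward timing: costs and utilities accrue at the end of each cycle
t = 1..horizon and are discounted by (1 + r)^(-t). The only cycle-0 reward is
the one-time CGM acquisition cost, which is not discounted. No half-cycle
correction is applied.

Competing-risk ordering within a cycle: the state-specific death probability
(baseline schedule x state multiplier) is applied first; complication
transitions use their annual probabilities directly; the self-transition
absorbs the remainder.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import TYPE_CHECKING, Mapping

import numpy as np

from .states import (
    N_STATES,
    State,
    TRANSITIONS,
)

if TYPE_CHECKING:  # pragma: no cover
    from .mortality import MortalitySchedule

__all__ = [
    "Arm",
    "Dominance",
    "ModelParameters",
    "CohortTrace",
    "ArmResult",
    "CEResult",
    "InvalidParameterSetError",
    "discount_factor",
    "state_annual_cost",
    "state_utility",
    "build_transition_matrix",
    "build_transition_matrices",
    "run_cohort",
    "life_expectancy",
    "compare_arms",
    "net_monetary_benefit",
]


class Arm(str, enum.Enum):
    SMBG = "SMBG"
    CGM = "CGM"


class Dominance(str, enum.Enum):
    NONE = "none"
    INTERVENTION_DOMINANT = "intervention_dominant"
    INTERVENTION_DOMINATED = "intervention_dominated"


class InvalidParameterSetError(ValueError):
    """Raised when exits plus death exceed 1 for some state and age."""


@dataclass(frozen=True)
class ModelParameters:
    """Complete point-estimate parameter set for one model evaluation.

    ``state_costs`` holds the *marginal* annual cost of each living state
    (zero for the no-complications state; composite-state marginals are sums
    of their component marginals, except blindness, ESRD and LEA which carry
    their own single marginal). The total annual cost of occupying a state is
    ``base_annual_cost + state_costs[state]`` plus the CGM annual cost in the
    CGM arm after cycle 0.
    """

    transition_probs: Mapping[tuple[State, State], float]
    state_costs: Mapping[State, float]
    base_annual_cost: float
    cgm_initial_cost: float
    cgm_annual_cost: float
    utilities: Mapping[State, float]
    age_disutility_per_year: float
    risk_reductions: Mapping[str, float]
    discount_rate: float = 0.03
    start_age: int = 40
    horizon: int = 33
    subsequent_lea_prob: float = 0.110
    years_since_diagnosis: float = 20.0

    def validate(self) -> None:
        for key, p in self.transition_probs.items():
            if not 0.0 <= p <= 1.0:
                raise InvalidParameterSetError(f"transition {key} = {p} outside [0, 1]")
        if self.base_annual_cost < 0 or self.cgm_initial_cost < 0 or self.cgm_annual_cost < 0:
            raise InvalidParameterSetError("costs must be non-negative")
        for s, c in self.state_costs.items():
            if c < 0:
                raise InvalidParameterSetError(f"marginal cost of {s.name} is negative")
        for s, u in self.utilities.items():
            if not 0.0 <= u <= 1.0:
                raise InvalidParameterSetError(f"utility of {s.name} = {u} outside [0, 1]")
        for c, rr in self.risk_reductions.items():
            if not 0.0 <= rr <= 1.0:
                raise InvalidParameterSetError(f"risk reduction for {c} = {rr} outside [0, 1]")
        if self.discount_rate < 0:
            raise InvalidParameterSetError("discount rate must be >= 0")
        if self.horizon < 0:
            raise InvalidParameterSetError("horizon must be >= 0")

    def with_horizon(self, horizon: int) -> "ModelParameters":
        return replace(self, horizon=horizon)


@dataclass(frozen=True)
class CohortTrace:
    """Cohort occupancy by cycle: rows are cycles 0..horizon, columns states."""

    occupancy: np.ndarray  # shape (horizon + 1, 13)

    def __post_init__(self) -> None:
        occ = np.asarray(self.occupancy, dtype=float)
        if occ.ndim != 2 or occ.shape[1] != N_STATES:
            raise ValueError(f"trace must have {N_STATES} state columns")
        object.__setattr__(self, "occupancy", occ)

    @property
    def n_cycles(self) -> int:
        return self.occupancy.shape[0] - 1

    def death_occupancy(self) -> np.ndarray:
        return self.occupancy[:, State.DEATH]

    def alive(self) -> np.ndarray:
        return 1.0 - self.death_occupancy()


@dataclass(frozen=True)
class ArmResult:
    arm: Arm
    discounted_cost: float
    discounted_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    life_years: float
    trace: CohortTrace


@dataclass(frozen=True)
class CEResult:
    """Incremental comparison of the CGM arm against the SMBG arm."""

    delta_cost: float
    delta_effect: float
    icer: float | None
    dominance: Dominance


def discount_factor(rate: float, t: int) -> float:
    """Present-value factor (1 + rate)^(-t) for an end-of-cycle-t reward."""
    if rate < 0:
        raise ValueError("discount rate must be >= 0")
    if t < 0:
        raise ValueError("cycle index must be >= 0")
    return (1.0 + rate) ** (-t)


def state_annual_cost(
    state: State, params: ModelParameters, arm: Arm, cycle: int = 1
) -> float:
    """Total annual cost of occupying a living state in a given arm/cycle."""
    if state is State.DEATH:
        raise ValueError("death state accrues no cost")
    if state not in params.state_costs:
        raise KeyError(f"no cost configured for state {state!r}")
    cost = params.base_annual_cost + params.state_costs[state]
    if arm is Arm.CGM and cycle >= 1:
        cost += params.cgm_annual_cost
    return cost


def state_utility(state: State, params: ModelParameters, age: float) -> float:
    """Age-adjusted utility weight of a living state (floored at 0)."""
    if state is State.DEATH:
        raise ValueError("death state has no utility weight")
    u = params.utilities[state] + (age - params.start_age) * params.age_disutility_per_year
    return max(u, 0.0)


def _exit_matrix(params: ModelParameters, arm: Arm) -> np.ndarray:
    """Off-diagonal living-to-living transition block (13 x 13).

    In the CGM arm every transition whose destination adds complication c
    is multiplied by (1 - risk_reduction[c]); risk reductions exist for
    retinopathy, nephropathy, neuropathy and CHD only.
    """
    E = np.zeros((N_STATES, N_STATES))
    rr = params.risk_reductions
    for src, dst, _, added in TRANSITIONS:
        p = params.transition_probs[(src, dst)]
        if arm is Arm.CGM and added in rr:
            p *= 1.0 - rr[added]
        E[src, dst] += p
    return E


def build_transition_matrices(
    params: ModelParameters,
    arm: Arm,
    ages: np.ndarray,
    mortality: "MortalitySchedule",
    cap_death_at_residual: bool = False,
) -> np.ndarray:
    """Row-stochastic transition matrices for each age, shape (n, 13, 13).

    Death probability from each living state is baseline_q(age) times the
    state's mortality multiplier, capped at 1; the self-transition absorbs
    whatever the listed exits and death leave over. A negative residual
    (exits + death > 1) is an invalid parameter set unless
    ``cap_death_at_residual`` is set, in which case death is capped at
    1 - exits (competing-risk cap, used for extended-horizon life-expectancy
    runs where constant exit probabilities meet extreme-age mortality).
    """
    ages = np.atleast_1d(np.asarray(ages))
    E = _exit_matrix(params, arm)
    exit_sums = E.sum(axis=1)
    if np.any(exit_sums > 1.0 + 1e-12):
        s = int(np.argmax(exit_sums))
        raise InvalidParameterSetError(
            f"exit probabilities from state {State(s).name} sum to {exit_sums[s]:.4g} > 1"
        )
    q = mortality.q_for(ages)  # (n,)
    mult = mortality.multiplier_vector()  # (13,), death entry 0
    death = np.minimum(q[:, None] * mult[None, :], 1.0)  # (n, 13)
    death[:, State.DEATH] = 0.0
    if cap_death_at_residual:
        death = np.minimum(death, np.clip(1.0 - exit_sums, 0.0, None)[None, :])
        death[:, State.DEATH] = 0.0
    stay = 1.0 - exit_sums[None, :] - death
    stay[:, State.DEATH] = 1.0
    if np.any(stay < -1e-12):
        i, s = np.argwhere(stay < -1e-12)[0]
        raise InvalidParameterSetError(
            f"exits plus death exceed 1 for state {State(s).name} at age {int(ages[i])} "
            f"(residual self-probability {stay[i, s]:.4g})"
        )
    stay = np.clip(stay, 0.0, None)
    M = np.broadcast_to(E, (len(ages), N_STATES, N_STATES)).copy()
    M[:, :, State.DEATH] = death
    idx = np.arange(N_STATES)
    M[:, idx, idx] = stay
    M[:, State.DEATH, State.DEATH] = 1.0
    return M


def build_transition_matrix(
    params: ModelParameters,
    arm: Arm,
    age: int,
    mortality: "MortalitySchedule",
) -> np.ndarray:
    """Row-stochastic 13 x 13 transition matrix at one age."""
    return build_transition_matrices(params, arm, np.array([age]), mortality)[0]


def run_cohort(
    params: ModelParameters,
    arm: Arm,
    mortality: "MortalitySchedule",
    cap_death_at_residual: bool = False,
) -> ArmResult:
    """Run the cohort from 100% no-complications through ``horizon`` cycles."""
    params.validate()
    horizon = params.horizon
    occ = np.zeros((horizon + 1, N_STATES))
    occ[0, State.NO_COMPLICATIONS] = 1.0

    disc_cost = undisc_cost = 0.0
    if arm is Arm.CGM:
        disc_cost = undisc_cost = params.cgm_initial_cost  # cycle 0, undiscounted

    if horizon > 0:
        ages = params.start_age + np.arange(horizon)  # age at the start of each cycle
        M = build_transition_matrices(
            params, arm, ages, mortality, cap_death_at_residual=cap_death_at_residual
        )
        for t in range(1, horizon + 1):
            occ[t] = occ[t - 1] @ M[t - 1]

    # cost/utility reward vectors; death accrues nothing
    living = np.array([s is not State.DEATH for s in State])
    cost_vec = np.zeros(N_STATES)
    for s in State:
        if s is not State.DEATH:
            cost_vec[s] = state_annual_cost(s, params, arm, cycle=1)
    t_idx = np.arange(1, horizon + 1)
    df = (1.0 + params.discount_rate) ** (-t_idx.astype(float))

    # utility matrix (cycle, state): tabulated utility minus age deduction
    u0 = np.array([params.utilities.get(s, 0.0) if s is not State.DEATH else 0.0 for s in State])
    u_cycle = u0[None, :] + (t_idx[:, None] * params.age_disutility_per_year)
    u_cycle = np.clip(u_cycle, 0.0, None)
    u_cycle[:, ~living] = 0.0

    body = occ[1:]
    cost_t = body @ cost_vec
    qaly_t = (body * u_cycle).sum(axis=1)
    alive_t = body[:, living].sum(axis=1)
    ones = np.ones_like(df)  # same accumulation path so rate=0 is exact

    return ArmResult(
        arm=arm,
        discounted_cost=disc_cost + float(cost_t @ df),
        discounted_qalys=float(qaly_t @ df),
        undiscounted_cost=undisc_cost + float(cost_t @ ones),
        undiscounted_qalys=float(qaly_t @ ones),
        life_years=float(alive_t.sum()),
        trace=CohortTrace(occ),
    )


def life_expectancy(
    params: ModelParameters,
    mortality: "MortalitySchedule",
    arm: Arm = Arm.SMBG,
) -> float:
    """Cohort life expectancy in years from the start age.

    Uses the model's end-of-cycle person-year convention (curtate expectation)
    over the full age range of the mortality schedule, so the 33-year analytic
    horizon does not truncate it.
    """
    horizon = int(mortality.ages.max() - params.start_age + 1)
    res = run_cohort(
        params.with_horizon(horizon), arm, mortality, cap_death_at_residual=True
    )
    return params.start_age + res.life_years


def compare_arms(smbg: ArmResult, cgm: ArmResult) -> CEResult:
    """Incremental cost-effectiveness of CGM over SMBG (discounted totals)."""
    d_cost = cgm.discounted_cost - smbg.discounted_cost
    d_eff = cgm.discounted_qalys - smbg.discounted_qalys
    if d_eff > 0 and d_cost <= 0 or (d_eff == 0 and d_cost < 0):
        return CEResult(d_cost, d_eff, None, Dominance.INTERVENTION_DOMINANT)
    if d_eff < 0 and d_cost >= 0 or (d_eff == 0 and d_cost > 0):
        return CEResult(d_cost, d_eff, None, Dominance.INTERVENTION_DOMINATED)
    if d_eff == 0:
        return CEResult(d_cost, d_eff, None, Dominance.NONE)
    return CEResult(d_cost, d_eff, d_cost / d_eff, Dominance.NONE)


def net_monetary_benefit(wtp: float, ce: CEResult) -> float:
    """NMB = WTP x ΔE - ΔC; positive means cost-effective at that WTP."""
    if wtp < 0:
        raise ValueError("willingness-to-pay must be >= 0")
    return wtp * ce.delta_effect - ce.delta_cost
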
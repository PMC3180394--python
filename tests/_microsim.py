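"""Independent individual-level Monte Carlo oracle for the cohort engine.

Samples whole state paths person by person from the same transition matrices
the cohort engine uses, but accrues rewards with its own arithmetic (written
directly from the parameter fields, not the engine's vectorised accrual), so
agreement checks the cohort algebra end to end.
"""

from __future__ import annotations

import numpy as np

from cgmcea.engine import Arm, ModelParameters, build_transition_matrices
from cgmcea.states import N_STATES, State


def microsimulate(
    params: ModelParameters,
    arm: Arm,
    mortality,
    n_individuals: int,
    seed: int,
):
    """Simulate individual paths; return mean and SE of discounted cost/QALYs.

    End-of-cycle rewards, discount (1+r)^-t, CGM initial cost at cycle 0
    undiscounted and CGM annual cost in every living state from cycle 1 on.
    """
    rng = np.random.default_rng(seed)
    horizon = params.horizon
    ages = params.start_age + np.arange(horizon)
    matrices = build_transition_matrices(params, arm, ages, mortality)
    cum = np.cumsum(matrices, axis=2)  # (horizon, 13, 13)

    cost_per_state = np.zeros(N_STATES)
    for s in State:
        if s is not State.DEATH:
            cost_per_state[s] = params.base_annual_cost + params.state_costs[s]
            if arm is Arm.CGM:
                cost_per_state[s] += params.cgm_annual_cost

    state = np.full(n_individuals, int(State.NO_COMPLICATIONS))
    cost = np.zeros(n_individuals)
    qaly = np.zeros(n_individuals)
    if arm is Arm.CGM:
        cost += params.cgm_initial_cost
    for t in range(1, horizon + 1):
        u = rng.random(n_individuals)
        state = (u[:, None] > cum[t - 1][state]).sum(axis=1)
        df = (1.0 + params.discount_rate) ** (-t)
        cost += df * cost_per_state[state]
        living = state != int(State.DEATH)
        utils = np.array(
            [
                max(params.utilities[s] + t * params.age_disutility_per_year, 0.0)
                if s is not State.DEATH
                else 0.0
                for s in State
            ]
        )
        qaly += df * np.where(living, utils[state], 0.0)

    return {
        "cost_mean": cost.mean(),
        "cost_se": cost.std(ddof=1) / np.sqrt(n_individuals),
        "qaly_mean": qaly.mean(),
        "qaly_se": qaly.std(ddof=1) / np.sqrt(n_individuals),
    }
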
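"""Point estimates, credible ranges and sampling distributions for every model
parameter.

Uncertain parameters are described by a mean and a 2.5%/97.5% credible range
and are sampled in the probabilistic sensitivity analysis from beta
distributions (probabilities, utilities, risk reductions) or gamma
distributions (costs). Distributions are fitted by the method of moments with
sd = (hi - lo)/3.92, which keeps the analytic mean exactly at the printed
mean; for the rare heavily skewed range this normal-width assumption misses
the printed bounds, so the fit then refines the concentration (mean held
fixed) until the implied 95% interval matches the printed one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import ModelParameters
from .states import State, TRANSITIONS

logger = logging.getLogger(__name__)

__all__ = [
    "ParameterSpec",
    "ParameterDraw",
    "InfeasibleFitError",
    "default_parameter_table",
    "fit_beta",
    "fit_gamma",
    "fitted_distribution",
    "build_parameters",
    "default_values",
    "sample_parameters",
    "table_to_csv",
    "table_from_csv",
]

BETA = "beta"
GAMMA = "gamma"
FIXED = "fixed"


class InfeasibleFitError(ValueError):
    """The requested (mean, range) admits no distribution in the family."""


@dataclass(frozen=True)
class ParameterSpec:
    """One uncertain (or fixed) model parameter."""

    name: str
    group: str  # probability | cost | utility | risk_reduction | setting
    mean: float
    lo: float | None = None
    hi: float | None = None
    family: str = FIXED
    label: str = ""

    def __post_init__(self) -> None:
        if self.family not in (BETA, GAMMA, FIXED):
            raise ValueError(f"unknown family {self.family!r}")
        if self.family != FIXED:
            if self.lo is None or self.hi is None:
                raise ValueError(f"{self.name}: ranged parameter needs lo and hi")
            if not self.lo <= self.mean <= self.hi:
                raise ValueError(f"{self.name}: mean outside [lo, hi]")


@dataclass(frozen=True)
class ParameterDraw:
    """One sampled parameter set, with the values that produced it."""

    values: dict[str, float]
    params: ModelParameters
    seed: int | None = None


def _t(name, label, mean, lo, hi):
    return ParameterSpec(name, "probability", mean, lo, hi, BETA, label)


def _c(name, label, mean, lo, hi):
    return ParameterSpec(name, "cost", mean, lo, hi, GAMMA, label)


def _u(name, label, mean, lo, hi):
    return ParameterSpec(name, "utility", mean, lo, hi, BETA, label)


def _r(name, label, mean, lo, hi):
    return ParameterSpec(name, "risk_reduction", mean, lo, hi, BETA, label)


def default_parameter_table() -> list[ParameterSpec]:
    """The model's published parameter table: 12 annual transition
    probabilities, 10 costs (2007 US$), 12 state utilities plus the fixed age
    disutility, 4 CGM relative risk reductions, and the fixed settings."""
    return [
        # --- annual transition probabilities ---
        _t("p_retinopathy_blindness", "Retinopathy to blindness", 0.101, 0.057, 0.156),
        _t("p_nocomp_chd", "Diabetes with no complications to CHD", 0.031, 0.018, 0.048),
        _t("p_subsequent_lea", "Subsequent LEA", 0.110, 0.062, 0.169),
        _t("p_nocomp_nephropathy", "Diabetes with no complications to nephropathy", 0.072, 0.041, 0.112),
        _t("p_nephropathy_chd", "Nephropathy to CHD", 0.022, 0.013, 0.034),
        _t("p_nephropathy_esrd", "Nephropathy to ESRD", 0.072, 0.041, 0.109),
        _t("p_nocomp_neuropathy", "Diabetes with no complications to neuropathy", 0.035, 0.020, 0.055),
        _t("p_neuropathy_chd", "Neuropathy to CHD", 0.029, 0.016, 0.044),
        _t("p_neuropathy_lea", "Neuropathy to LEA", 0.131, 0.074, 0.200),
        _t("p_neuropathy_nephropathy", "Neuropathy to nephropathy", 0.097, 0.055, 0.149),
        _t("p_nocomp_retinopathy", "Diabetes with no complications to retinopathy", 0.011, 0.006, 0.017),
        _t("p_retinopathy_chd", "Retinopathy to CHD", 0.028, 0.016, 0.043),
        # --- annual / initial costs, 2007 US$ ---
        _c("c_blindness", "Blindness and retinopathy cost", 9912, 7251, 12945),
        _c("c_cgm_annual", "CGM technology annual cost", 4189, 3062, 5492),
        _c("c_cgm_initial", "Initial cost of CGM technology", 4809, 3499, 6321),
        _c("c_chd", "CHD cost", 35271, 25820, 46433),
        _c("c_no_complications", "Diabetes with no complications cost", 6705, 4879, 8788),
        _c("c_esrd", "ESRD cost", 36370, 26377, 47708),
        _c("c_lea", "LEA cost", 50150, 36541, 65798),
        _c("c_nephropathy", "Nephropathy cost", 20161, 14614, 26643),
        _c("c_neuropathy", "Neuropathy cost", 25075, 18226, 33004),
        _c("c_retinopathy", "Retinopathy cost", 4956, 3578, 6489),
        # --- EQ-5D utilities at age 40 ---
        _u("u_blindness", "Utility of blindness", 0.569, 0.531, 0.607),
        _u("u_chd", "Utility of CHD", 0.552, 0.513, 0.591),
        _u("u_esrd", "Utility of ESRD", 0.521, 0.485, 0.558),
        _u("u_lea", "Utility of LEA", 0.572, 0.538, 0.604),
        _u("u_nephropathy", "Utility of nephropathy", 0.575, 0.545, 0.606),
        _u("u_nephropathy_chd", "Utility of nephropathy and CHD", 0.516, 0.465, 0.567),
        _u("u_neuropathy", "Utility of neuropathy", 0.603, 0.573, 0.632),
        _u("u_neuropathy_chd", "Utility of neuropathy and CHD", 0.544, 0.495, 0.593),
        _u("u_neuropathy_nephropathy", "Utility of neuropathy and nephropathy", 0.557, 0.520, 0.595),
        _u("u_no_complications", "Utility of diabetes with no complications", 0.757, 0.747, 0.767),
        _u("u_retinopathy", "Utility of retinopathy", 0.612, 0.581, 0.643),
        _u("u_retinopathy_chd", "Utility of retinopathy and CHD", 0.553, 0.503, 0.605),
        ParameterSpec("du_age", "utility", -0.0003, family=FIXED, label="Disutility of age"),
        # --- CGM relative risk reductions (from the 0.5% A1c effect) ---
        _r("rrr_chd", "CGM risk reduction for CHD", 0.050, 0.013, 0.107),
        _r("rrr_nephropathy", "CGM risk reduction for nephropathy", 0.270, 0.006, 0.768),
        _r("rrr_neuropathy", "CGM risk reduction for neuropathy", 0.188, 0.004, 0.593),
        _r("rrr_retinopathy", "CGM risk reduction for retinopathy", 0.306, 0.075, 0.618),
        # --- fixed settings ---
        ParameterSpec("start_age", "setting", 40, family=FIXED, label="Start age"),
        ParameterSpec("years_since_diagnosis", "setting", 20, family=FIXED, label="Years since diagnosis"),
        ParameterSpec("discount_rate", "setting", 0.03, family=FIXED, label="Discount rate"),
        ParameterSpec("horizon", "setting", 33, family=FIXED, label="Time horizon (years)"),
    ]


def _percentile_miss(dist, lo: float, hi: float) -> float:
    q = dist.ppf([0.025, 0.975])
    return max(abs(q[0] - lo) / abs(lo), abs(q[1] - hi) / abs(hi))


def fit_beta(
    mean: float, lo: float, hi: float, refine_threshold: float = 0.15
) -> tuple[float, float]:
    """Beta shape parameters from a mean and 95% credible range.

    Method of moments with sd = (hi - lo)/3.92. If the implied 2.5/97.5
    percentiles miss the stated bounds by more than ``refine_threshold``
    (relative), the concentration alpha+beta is re-optimised with the mean
    held exact so the fitted interval tracks the stated one.
    """
    if not 0.0 < mean < 1.0:
        raise InfeasibleFitError(f"beta mean {mean} outside (0, 1)")
    if not lo < hi:
        raise InfeasibleFitError(f"degenerate range [{lo}, {hi}]: treat as point mass")
    sd = (hi - lo) / 3.92
    var = sd * sd
    if var >= mean * (1.0 - mean):
        raise InfeasibleFitError(
            f"variance {var:.4g} >= mean(1-mean) = {mean * (1 - mean):.4g}; no beta exists"
        )
    k = mean * (1.0 - mean) / var - 1.0
    alpha, beta_shape = mean * k, (1.0 - mean) * k
    if _percentile_miss(stats.beta(alpha, beta_shape), lo, hi) > refine_threshold:
        res = optimize.minimize_scalar(
            lambda logk: _percentile_miss(
                stats.beta(mean * np.exp(logk), (1 - mean) * np.exp(logk)), lo, hi
            ),
            bounds=(np.log(0.01), np.log(1e6)),
            method="bounded",
        )
        k = float(np.exp(res.x))
        alpha, beta_shape = mean * k, (1.0 - mean) * k
    return alpha, beta_shape


def fit_gamma(
    mean: float, lo: float, hi: float, refine_threshold: float = 0.15
) -> tuple[float, float]:
    """Gamma (shape, scale) from a mean and 95% credible range.

    shape = (mean/sd)^2, scale = sd^2/mean with sd = (hi - lo)/3.92; same
    mean-preserving percentile refinement as :func:`fit_beta`.
    """
    if mean <= 0:
        raise InfeasibleFitError(f"gamma mean {mean} must be positive")
    if not lo < hi:
        raise InfeasibleFitError(f"degenerate range [{lo}, {hi}]: treat as point mass")
    sd = (hi - lo) / 3.92
    if sd <= 0:
        raise InfeasibleFitError("non-positive sd: treat as point mass")
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    if _percentile_miss(stats.gamma(shape, scale=scale), lo, hi) > refine_threshold:
        res = optimize.minimize_scalar(
            lambda logs: _percentile_miss(
                stats.gamma(np.exp(logs), scale=mean / np.exp(logs)), lo, hi
            ),
            bounds=(np.log(0.01), np.log(1e6)),
            method="bounded",
        )
        shape = float(np.exp(res.x))
        scale = mean / shape
    return shape, scale


def fitted_distribution(spec: ParameterSpec):
    """Frozen scipy distribution for a ranged spec, or None for a point mass."""
    if spec.family == FIXED:
        return None
    try:
        if spec.family == BETA:
            a, b = fit_beta(spec.mean, spec.lo, spec.hi)
            return stats.beta(a, b)
        shape, scale = fit_gamma(spec.mean, spec.lo, spec.hi)
        return stats.gamma(shape, scale=scale)
    except InfeasibleFitError as err:
        warnings.warn(
            f"{spec.name}: infeasible {spec.family} fit ({err}); using point mass",
            stacklevel=2,
        )
        return None


def default_values() -> dict[str, float]:
    """Point-estimate value for every parameter, keyed by name."""
    return {spec.name: float(spec.mean) for spec in default_parameter_table()}


# marginal annual cost of each living state in terms of the cost parameters;
# composite-state marginals are recomputed from the drawn component costs,
# while blindness, ESRD and LEA carry their own single marginal
_MARGINAL_COST_TERMS: dict[State, tuple[str, ...]] = {
    State.NO_COMPLICATIONS: (),
    State.RETINOPATHY: ("c_retinopathy",),
    State.NEPHROPATHY: ("c_nephropathy",),
    State.NEUROPATHY: ("c_neuropathy",),
    State.CHD: ("c_chd",),
    State.BLINDNESS: ("c_blindness",),
    State.ESRD: ("c_esrd",),
    State.LEA: ("c_lea",),
    State.NEPHROPATHY_CHD: ("c_nephropathy", "c_chd"),
    State.NEUROPATHY_CHD: ("c_neuropathy", "c_chd"),
    State.RETINOPATHY_CHD: ("c_retinopathy", "c_chd"),
    State.NEUROPATHY_NEPHROPATHY: ("c_neuropathy", "c_nephropathy"),
}

_UTILITY_KEYS: dict[State, str] = {
    State.NO_COMPLICATIONS: "u_no_complications",
    State.RETINOPATHY: "u_retinopathy",
    State.NEPHROPATHY: "u_nephropathy",
    State.NEUROPATHY: "u_neuropathy",
    State.CHD: "u_chd",
    State.BLINDNESS: "u_blindness",
    State.ESRD: "u_esrd",
    State.LEA: "u_lea",
    State.NEPHROPATHY_CHD: "u_nephropathy_chd",
    State.NEUROPATHY_CHD: "u_neuropathy_chd",
    State.RETINOPATHY_CHD: "u_retinopathy_chd",
    State.NEUROPATHY_NEPHROPATHY: "u_neuropathy_nephropathy",
}

_RRR_KEYS = {
    "CHD": "rrr_chd",
    "nephropathy": "rrr_nephropathy",
    "neuropathy": "rrr_neuropathy",
    "retinopathy": "rrr_retinopathy",
}


def build_parameters(
    values: Mapping[str, float] | None = None, **overrides: float
) -> ModelParameters:
    """Assemble a :class:`ModelParameters` from named parameter values.

    Missing names take their point estimates. Composite-state marginal costs
    are recomputed by summation from the component cost values.
    """
    vals = default_values()
    if values:
        unknown = set(values) - set(vals)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        vals.update(values)
    if overrides:
        unknown = set(overrides) - set(vals)
        if unknown:
            raise KeyError(f"unknown parameter name(s): {sorted(unknown)}")
        vals.update(overrides)

    transition_probs = {
        (src, dst): vals[pname] for src, dst, pname, _ in TRANSITIONS
    }
    state_costs = {
        s: sum(vals[k] for k in terms) for s, terms in _MARGINAL_COST_TERMS.items()
    }
    utilities = {s: vals[k] for s, k in _UTILITY_KEYS.items()}
    risk_reductions = {c: vals[k] for c, k in _RRR_KEYS.items()}
    return ModelParameters(
        transition_probs=transition_probs,
        state_costs=state_costs,
        base_annual_cost=vals["c_no_complications"],
        cgm_initial_cost=vals["c_cgm_initial"],
        cgm_annual_cost=vals["c_cgm_annual"],
        utilities=utilities,
        age_disutility_per_year=vals["du_age"],
        risk_reductions=risk_reductions,
        discount_rate=vals["discount_rate"],
        start_age=int(vals["start_age"]),
        horizon=int(vals["horizon"]),
        subsequent_lea_prob=vals["p_subsequent_lea"],
        years_since_diagnosis=vals["years_since_diagnosis"],
    )


def sample_parameters(
    specs: Sequence[ParameterSpec], rng: np.random.Generator
) -> ParameterDraw:
    """One joint draw: independent samples per ranged parameter, fixed values
    passed through, composite costs recomputed from the drawn components."""
    values: dict[str, float] = {}
    for spec in specs:
        dist = fitted_distribution(spec)
        if dist is None:
            values[spec.name] = float(spec.mean)
        else:
            values[spec.name] = float(dist.rvs(random_state=rng))
    return ParameterDraw(values=values, params=build_parameters(values))


def table_to_csv(specs: Iterable[ParameterSpec], path) -> None:
    pd.DataFrame(
        [
            {
                "name": s.name,
                "group": s.group,
                "mean": s.mean,
                "lo": s.lo,
                "hi": s.hi,
                "family": s.family,
                "label": s.label,
            }
            for s in specs
        ]
    ).to_csv(path, index=False)


def table_from_csv(path) -> list[ParameterSpec]:
    df = pd.read_csv(path)
    specs = []
    for row in df.itertuples(index=False):
        lo = None if pd.isna(row.lo) else float(row.lo)
        hi = None if pd.isna(row.hi) else float(row.hi)
        label = "" if not hasattr(row, "label") or pd.isna(row.label) else str(row.label)
        specs.append(
            ParameterSpec(row.name, row.group, float(row.mean), lo, hi, row.family, label)
        )
    return specs
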
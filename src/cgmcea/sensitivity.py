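"""Probabilistic and univariate sensitivity analyses over the cohort engine.

The probabilistic analysis samples all uncertain parameters jointly (beta for
probabilities/utilities/risk reductions, gamma for costs), applies each draw
to both arms (common random parameters), and records per-iteration discounted
cost and QALYs. Univariate analysis perturbs one parameter at a time by a
fixed percentage and ranks parameters by the spread of the resulting net
monetary benefit; the top-ranked parameters are then probed at +/-50%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .engine import (
    Arm,
    CEResult,
    InvalidParameterSetError,
    compare_arms,
    net_monetary_benefit,
    run_cohort,
)
from .mortality import MortalitySchedule
from .parameters import (
    FIXED,
    BETA,
    ParameterSpec,
    build_parameters,
    fitted_distribution,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PSAResult",
    "TornadoEntry",
    "run_psa",
    "quadrant_fractions",
    "quadrant_partition",
    "ceac",
    "tornado",
    "probe_icer",
    "DEFAULT_TORNADO_WTP",
]

#: WTP used to rank one-way NMB spreads (configurable in every entry point).
DEFAULT_TORNADO_WTP = 100_000.0


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration PSA records with the seed that produced them.

    ``draws`` columns: cost_smbg, qaly_smbg, cost_cgm, qaly_cgm, delta_cost,
    delta_effect.
    """

    draws: pd.DataFrame
    seed: int
    n_redraws: int = 0

    @property
    def n_iterations(self) -> int:
        return len(self.draws)

    def delta(self) -> tuple[np.ndarray, np.ndarray]:
        return (
            self.draws["delta_cost"].to_numpy(),
            self.draws["delta_effect"].to_numpy(),
        )


@dataclass(frozen=True)
class TornadoEntry:
    parameter: str
    label: str
    nmb_low: float
    nmb_high: float
    spread: float = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "spread", abs(self.nmb_high - self.nmb_low))


def _run_both_arms(params, mortality) -> tuple[float, float, float, float]:
    smbg = run_cohort(params, Arm.SMBG, mortality)
    cgm = run_cohort(params, Arm.CGM, mortality)
    return (
        smbg.discounted_cost,
        smbg.discounted_qalys,
        cgm.discounted_cost,
        cgm.discounted_qalys,
    )


def run_psa(
    specs: Sequence[ParameterSpec],
    mortality: MortalitySchedule,
    n: int,
    seed: int,
    max_redraw_fraction: float = 0.01,
) -> PSAResult:
    """Monte Carlo PSA: ``n`` joint parameter draws, both arms per draw.

    Iterations whose draw yields an invalid transition matrix (exits plus
    death exceeding 1 for some state/age) are redrawn and counted; the run
    aborts if more than ``max_redraw_fraction`` of iterations needed a redraw.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    dists = {spec.name: fitted_distribution(spec) for spec in specs}
    # sample every parameter up front, one vectorised stream per spec
    samples = {}
    for spec in specs:
        d = dists[spec.name]
        if d is None:
            samples[spec.name] = np.full(n, float(spec.mean))
        else:
            samples[spec.name] = d.rvs(size=n, random_state=rng)

    records = np.empty((n, 4))
    n_redraws = 0
    for i in range(n):
        values = {name: float(col[i]) for name, col in samples.items()}
        while True:
            try:
                params = build_parameters(values)
                records[i] = _run_both_arms(params, mortality)
                break
            except InvalidParameterSetError as err:
                n_redraws += 1
                if n_redraws > max_redraw_fraction * n:
                    raise RuntimeError(
                        f"more than {max_redraw_fraction:.0%} of PSA iterations "
                        f"required redraws (last: {err})"
                    ) from err
                logger.warning("PSA iteration %d redrawn: %s", i, err)
                values = {
                    spec.name: (
                        float(spec.mean)
                        if dists[spec.name] is None
                        else float(dists[spec.name].rvs(random_state=rng))
                    )
                    for spec in specs
                }

    df = pd.DataFrame(
        records, columns=["cost_smbg", "qaly_smbg", "cost_cgm", "qaly_cgm"]
    )
    df["delta_cost"] = df["cost_cgm"] - df["cost_smbg"]
    df["delta_effect"] = df["qaly_cgm"] - df["qaly_smbg"]
    return PSAResult(draws=df, seed=seed, n_redraws=n_redraws)


def quadrant_fractions(psa: PSAResult, wtp: float) -> dict[str, float]:
    """Cost-effectiveness plane summaries at one WTP threshold.

    fraction_SE: cheaper and more effective (ΔC < 0, ΔE > 0) — dominant;
    fraction_NE_below_wtp: costlier but more effective with ICER below WTP;
    fraction_cost_effective: positive net monetary benefit.
    Points on the ΔC = 0 axis count as NE; ΔE = 0 points belong to neither
    SE nor NE.
    """
    d_cost, d_eff = psa.delta()
    if d_cost.size == 0:
        raise ValueError("empty PSA result")
    se = (d_cost < 0) & (d_eff > 0)
    ne_below = (d_cost >= 0) & (d_eff > 0) & (d_cost < wtp * d_eff)
    nmb = wtp * d_eff - d_cost
    return {
        "fraction_SE": float(se.mean()),
        "fraction_NE_below_wtp": float(ne_below.mean()),
        "fraction_cost_effective": float((nmb > 0).mean()),
    }


def quadrant_partition(psa: PSAResult) -> dict[str, float]:
    """Fractions in the four CE-plane quadrants (a partition summing to 1).

    Axis rule: ΔC = 0 counts as the non-negative-cost side (NE/NW); ΔE = 0
    counts as the non-positive-effect side (NW/SW).
    """
    d_cost, d_eff = psa.delta()
    return {
        "NE": float(((d_cost >= 0) & (d_eff > 0)).mean()),
        "SE": float(((d_cost < 0) & (d_eff > 0)).mean()),
        "NW": float(((d_cost >= 0) & (d_eff <= 0)).mean()),
        "SW": float(((d_cost < 0) & (d_eff <= 0)).mean()),
    }


def ceac(psa: PSAResult, wtp_grid: Sequence[float]) -> pd.DataFrame:
    """Cost-effectiveness acceptability curve: P(NMB > 0) per WTP value."""
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if np.any(np.diff(wtp_grid) < 0):
        raise ValueError("wtp_grid must be sorted ascending")
    d_cost, d_eff = psa.delta()
    probs = [
        float(((wtp * d_eff - d_cost) > 0).mean()) for wtp in wtp_grid
    ]
    return pd.DataFrame({"wtp": wtp_grid, "probability_cost_effective": probs})


def _perturbed_value(spec: ParameterSpec, factor: float) -> float:
    """Parameter value scaled by ``factor``, clipped to the family support."""
    value = spec.mean * factor
    if spec.family == BETA and not 0.0 <= value <= 1.0:
        clipped = float(np.clip(value, 0.0, 1.0))
        logger.warning(
            "%s perturbed to %.4g, clipped to %.4g (beta support)",
            spec.name, value, clipped,
        )
        value = clipped
    return value


def tornado(
    specs: Sequence[ParameterSpec],
    mortality: MortalitySchedule,
    wtp: float = DEFAULT_TORNADO_WTP,
    pct: float = 0.15,
) -> list[TornadoEntry]:
    """One-way NMB screen: every ranged parameter at mean*(1-pct) and
    mean*(1+pct), others at their means; entries sorted by spread descending."""
    if not 0.0 <= pct < 1.0:
        raise ValueError("pct must be in [0, 1)")
    entries = []
    for spec in specs:
        if spec.family == FIXED:
            continue
        nmbs = []
        for factor in (1.0 - pct, 1.0 + pct):
            params = build_parameters({spec.name: _perturbed_value(spec, factor)})
            smbg = run_cohort(params, Arm.SMBG, mortality)
            cgm = run_cohort(params, Arm.CGM, mortality)
            nmbs.append(net_monetary_benefit(wtp, compare_arms(smbg, cgm)))
        entries.append(TornadoEntry(spec.name, spec.label, nmbs[0], nmbs[1]))
    entries.sort(key=lambda e: e.spread, reverse=True)
    return entries


def probe_icer(
    param_name: str,
    factor: float,
    specs: Sequence[ParameterSpec],
    mortality: MortalitySchedule,
) -> CEResult:
    """Base case with one parameter multiplied by ``factor`` (support-clipped)."""
    if factor <= 0:
        raise ValueError("factor must be positive")
    spec = next((s for s in specs if s.name == param_name), None)
    if spec is None:
        raise KeyError(f"unknown parameter {param_name!r}")
    params = build_parameters({param_name: _perturbed_value(spec, factor)})
    smbg = run_cohort(params, Arm.SMBG, mortality)
    cgm = run_cohort(params, Arm.CGM, mortality)
    return compare_arms(smbg, cgm)


def tornado_to_frame(entries: Sequence[TornadoEntry]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": e.parameter,
                "label": e.label,
                "nmb_low": e.nmb_low,
                "nmb_high": e.nmb_high,
                "spread": e.spread,
                "rank": i + 1,
            }
            for i, e in enumerate(entries)
        ]
    )
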
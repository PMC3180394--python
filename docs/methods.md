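# Methods

## Model structure and assumptions

The engine is a deterministic Markov cohort model: a probability vector over
13 health states is propagated through age-dependent, row-stochastic 13×13
transition matrices for 33 annual cycles, starting with the whole cohort in
the no-complications state at age 40. The state space separates four
first-stage complications (retinopathy, nephropathy, neuropathy, CHD) from
seven second-stage states (blindness, ESRD, LEA and four two-complication
composites); second-stage states are terminal apart from death. All
transition probabilities are constant over time — there is no
duration-in-state or age dependence in complication risk, only in mortality.
Hypoglycaemic events and hypertension control are outside the model.

The CGM arm differs from the SMBG arm in exactly two ways: (i) each
transition whose destination state *adds* one of the four reducible
complications is multiplied by `1 − RRR` for that complication (the RRRs
derive from a 0.5% A1c reduction); (ii) the CGM device costs are added — the
acquisition cost once at cycle 0 (undiscounted) and the annual cost in every
living state from cycle 1 on. Mortality is never modified directly by CGM;
any survival gain arises from delayed entry into states with hazard
multipliers above 1.

Competing risks within a cycle are ordered death-first: the state's death
probability is `min(q(age) × multiplier, 1)`, the tabulated exits are applied
at face value, and the self-transition takes the remainder. A parameter set
for which exits plus death exceed 1 at any age in the analytic range is
rejected as invalid (and redrawn inside the PSA).

Rewards (costs in 2007 US$, EQ-5D utilities) accrue at the end of each cycle
`t = 1..33` with discount factor `(1 + r)^{−t}`, `r = 0.03`. No half-cycle
correction is applied; the only cycle-0 quantity is the CGM acquisition cost.
State utility at cycle `t` is the tabulated utility minus `0.0003·t` (the age
disutility), floored at 0 — a purely defensive floor, unreachable over 33
years. State cost is a base annual diabetes cost ($6,705) plus a marginal:
composite states sum their components' marginals (e.g. nephropathy+CHD =
$20,161 + $35,271), while blindness, ESRD and LEA carry single marginals.
The "subsequent LEA" probability (0.110) is represented as a self-transition
within the LEA state with no additional cost or utility consequence, since
the LEA annual cost already recurs; a repeat-amputation event cost would be a
straightforward extension but is not modelled.

## Parameters and sampling distributions

`parameters.default_parameter_table()` holds the full published table: 12
annual transition probabilities, 10 costs, 12 state utilities plus the fixed
age disutility, 4 CGM risk reductions, and the fixed settings (start age 40,
20 years since diagnosis, discount rate 3%, horizon 33). Each ranged
parameter carries a mean and a 2.5%/97.5% bound.

For the PSA, probabilities, utilities and risk reductions are sampled from
beta distributions and costs from gamma distributions, fitted by the method
of moments with `sd = (hi − lo)/3.92` (a normal-width reading of the 95%
range). This keeps the analytic mean exactly at the printed mean. For almost
every row the implied 2.5/97.5 percentiles then land within a few percent of
the printed bounds; the exception is the heavily right-skewed risk-reduction
rows (e.g. nephropathy RRR 0.270 with range 0.006–0.768), where a
symmetric-width variance cannot reproduce an asymmetric interval. For any row
whose moment-fitted percentiles miss the printed bounds by more than 15%, the
fit therefore re-optimises the concentration (beta `α+β`, or the gamma shape)
with the mean held exact, minimising the worst relative percentile error;
this brings those rows' implied intervals within ~1% of the printed ones
while leaving every other row's moment fit untouched. Parameters are sampled
independently (no correlation structure is published); composite-state
*costs* are recomputed from the drawn component costs via the summation rule,
whereas composite-state *utilities* are drawn directly from their own rows,
which carry their own credible ranges. Mortality is not varied in the PSA.

## Synthetic mortality schedule

The model needs an all-cause baseline death probability per age plus a hazard
multiplier per state. The real tables behind the original analysis (CDC
all-cause rates averaged over race/sex categories; ETDRS excess risks) are in
an unavailable supplement, so the package generates a synthetic stand-in and
also loads real schedules from CSV (`age, baseline_q`, one constant column
per state category; missing composite columns are filled with the maximum of
the component multipliers — a conservative rule that avoids double-counting).

The generated baseline is Gompertz, `q(age) = 1 − exp(−a·e^{b·age})` clipped
to `[0, 0.999]`, with slope `b = 0.085` per year (a typical adult value) and
level `a` calibrated by bisection on `log a` so the SMBG cohort's life
expectancy from age 40 equals 73 years (the anchor implied by the 33-year
horizon) to within ±0.05 years. Life expectancy uses the engine's end-of-cycle
(curtate) person-year convention on an extended horizon (to age 115) so the
analytic horizon does not truncate it; on those extended runs the death
probability is capped at `1 − exits` (a competing-risk cap), because constant
exit probabilities combined with extreme-age mortality would otherwise make
rows infeasible above roughly age 105 — the cap affects only the tiny
surviving tail and is not used in 33-cycle analytic runs. The default state
multipliers ({retinopathy 1.2, neuropathy 1.5, nephropathy 2.0, CHD 2.5,
blindness 1.3, ESRD 4.0, LEA 3.0}, composites = max of components) are
plausibility-ordered placeholders, *not* published values, and are
overridable via the CSV interface or the `multipliers` arguments.

What the synthetic schedule does and does not emulate: it reproduces the
qualitative features the model depends on (monotone age gradient, state
ordering of excess mortality, a life expectancy consistent with the model's
horizon), but not the actual level-by-age profile or the true excess-risk
magnitudes. Results that depend only on model structure (conservation,
arm equivalence under null effects, discounting identities, distribution
round-trips, microsimulation agreement) are unaffected by this substitution;
the absolute and incremental cost/QALY values are not, and should be read as
properties of the synthetic schedule, not of the original data. In
particular, under this schedule (and, as far as we could determine, under
*any* schedule combined with this 13-state structure) the incremental
results are materially less favourable to CGM than the original report: the
no-complications state has the highest CHD entry probability of any source
state, so keeping the cohort complication-free does not reduce CHD occupancy,
and the incremental QALY gain saturates near 0.3 regardless of the mortality
multipliers. Reproducing the original incrementals appears to require
unpublished structure (e.g. deeper multi-comorbidity progression states)
and/or the original mortality tables.

## Numerical choices

* Transition matrices are built vectorised over ages; rows sum to 1 to
  1e-12 by construction and the cohort trace conserves probability to 1e-9.
* Residual self-probabilities in `[−1e-12, 0)` from floating-point
  cancellation are clipped to 0; anything more negative raises an invalid
  parameter set error naming the state and age.
* The ICER is reported as undefined (`None`) under dominance or when
  `ΔE = 0`; dominance requires strict improvement in one dimension and no
  worsening in the other.
* Quadrant counting on the CE plane: points with `ΔC = 0` count as
  north (NE/NW); points with `ΔE = 0` count as west (NW/SW), so the four
  quadrants always partition the draws.
* Tornado perturbations of beta-bounded parameters are clipped to `[0, 1]`
  with a logged notice (the no-complications utility at +15% exceeds 1 and is
  clipped).
* The tornado's NMB ranking uses a default willingness-to-pay of
  $100,000/QALY (configurable); the screen perturbs ranged parameters only,
  leaving start age, horizon and discount rate fixed.
* PSA iterations whose draw is infeasible are redrawn and counted; the run
  aborts if more than 1% of iterations redraw (none do at the published
  ranges). All sampling is driven by a single `numpy` Generator seeded from
  the user-supplied seed, so every result is bit-reproducible.

## Problem sizes

The deterministic base case runs 33 cycles over 13 states (<1 ms). The PSA
default is 10,000 iterations (two cohort runs each, a few seconds). The
microsimulation cross-check samples 200,000 individual paths from the same
matrices with independent reward arithmetic and agrees with the cohort engine
within 3 standard errors of its mean.

## Known limitations

* The mortality schedule is synthetic (see above); absolute results are
  schedule-dependent.
* No duration-dependent risks, no states with more than two complications,
  no hypoglycaemia or hypertension sub-models.
* Parameter draws are independent; correlated elicitation is not supported.
* The repeat-amputation probability is cost- and utility-neutral.
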
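# cgmcea

A Markov cohort cost-utility model of **continuous glucose monitoring (CGM)
added to self-monitoring of blood glucose (SMBG)** versus SMBG alone in adults
with type 1 diabetes, re-implementing a published decision-analytic model as a
tested Python library with reproducible analysis scripts.

It is written for health-economics and HTA analysts who want a transparent,
scriptable state-transition engine: every transition probability, cost and
utility is an explicit named parameter, and the deterministic engine, the
probabilistic sensitivity analysis (PSA) and the tornado screen are ordinary
functions that can be driven from Python, from the `cgmcea` command line, or
from the numbered scripts under `analysis/`.

## The model

A closed cohort (start age 40, ~20 years since diagnosis) moves through 13
health states in annual cycles over a 33-year horizon:

* diabetes with no complications;
* four first-stage complications — retinopathy, nephropathy, neuropathy,
  coronary heart disease (CHD);
* seven second-stage states — blindness, end-stage renal disease (ESRD),
  lower-extremity amputation (LEA), and the composites nephropathy+CHD,
  neuropathy+CHD, retinopathy+CHD, neuropathy+nephropathy — which permit no
  exit other than death;
* death.

Within each cycle the state-specific death probability (an all-cause baseline
`q(age)` times a state hazard multiplier) applies first, the tabulated annual
transition probabilities apply to the listed exits, and the self-transition
absorbs the remainder. CGM acts only through relative risk reductions (RRRs)
on the *incidence* of retinopathy, nephropathy, neuropathy and CHD — every
transition whose destination adds complication `c` is scaled by
`1 − RRR_c` in the CGM arm — plus its device costs (a one-time acquisition
cost at cycle 0 and an annual cost in every living state thereafter).

Rewards accrue at the end of each cycle `t = 1..33` and are discounted by
`(1.03)^(−t)`. Per-arm results are summarised as discounted cost `C` and
QALYs `E`; strategies are compared by the incremental cost-effectiveness
ratio `ICER = ΔC/ΔE` and the net monetary benefit `NMB(λ) = λ·ΔE − ΔC` at a
willingness-to-pay `λ`.

Uncertain parameters carry a mean and 95% credible range; the PSA samples
them jointly from beta (probabilities, utilities, RRRs) and gamma (costs)
distributions fitted by the method of moments, and summarises the draw cloud
by cost-effectiveness plane quadrants and the acceptability curve (CEAC).

The published mortality appendix underlying the original model is not
available, so `cgmcea.mortality` provides a clearly-labelled **synthetic**
stand-in: a Gompertz baseline `q(a) = 1 − exp(−a·e^{b·age})` calibrated by
bisection so the SMBG cohort's life expectancy from age 40 is 73 years, with
placeholder state multipliers that can be overridden or replaced by a real
schedule via a simple CSV format.

## Worked example

```python
from cgmcea import (Arm, build_parameters, calibrate_baseline,
                    compare_arms, run_cohort)

params = build_parameters()               # the published point estimates
schedule = calibrate_baseline(73.0)       # synthetic mortality, LE 73
smbg = run_cohort(params, Arm.SMBG, schedule)
cgm = run_cohort(params, Arm.CGM, schedule)
ce = compare_arms(smbg, cgm)
print(f"SMBG ${smbg.discounted_cost:,.0f} / {smbg.discounted_qalys:.3f} QALYs")
print(f"CGM  ${cgm.discounted_cost:,.0f} / {cgm.discounted_qalys:.3f} QALYs")
print(f"ICER ${ce.icer:,.0f}/QALY")
```

prints

```
SMBG $615,960 / 11.131 QALYs
CGM  $664,593 / 11.419 QALYs
ICER $168,671/QALY
```

i.e. under the synthetic mortality schedule CGM gains 0.288 discounted QALYs
for $48,633, an ICER of about $169,000 per QALY. (With the original,
unpublished mortality tables the source analysis reported a considerably more
favourable ICER; see `docs/methods.md` for why the synthetic substitution
shifts the incrementals.) The same numbers come from the command line:

```bash
cgmcea run --out results
cgmcea psa --seed 1 --iterations 10000 --wtp 50000 --wtp 100000 --out results
cgmcea tornado --out results
cgmcea generate-mortality --target 73 --out results/mortality.csv
```

or from the narrative drivers `analysis/01_base_case.py`,
`analysis/02_psa.py` and `analysis/03_tornado.py`, which write their tables
under `results/`.

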
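# smokesim

A system-dynamics simulation of adolescent cigarette smoking and
tobacco-control policy, calibrated to the North Dakota setting: a
two-cohort aging-chain stock-and-flow model with social-pressure,
secondhand-smoke, nicotine-dependence, risk-perception and
marketing/policy feedback, plus the machinery around it — calibration
to a historical prevalence series, one-at-a-time sensitivity
validation, policy experiments, and a synthetic-data generator so the
whole pipeline runs offline from a single seed.

It is written for epidemiologists and health-policy modelers who want
a transparent, testable alternative to opaque graphical SD tools:
every equation is ordinary Python, every run is reproducible, and
every feedback loop can be switched off.

## The model

Middle-school (ages 11–14) and high-school (ages 15–18) cohorts are
simulated in parallel over 1992–2032. Within each cohort five mutually
exclusive stocks partition the population by smoking status:

    never smokers → current experimenters → current smokers
                        ↓         ↑↓             ↓↑
                 former experimenters         ex-smokers

Experimenters have smoked fewer than 100 cigarettes lifetime; smokers
100 or more — so no flow ever returns a smoker to an experimenter
stock. "Current" means any smoking in the past 30 days, and the
outcome of interest is the past-30-day smoking rate averaged across
the two cohorts. Each cohort spans four years: every stock graduates
to the next cohort (or out of the model) at ¼ of its level per year,
while new 11-year-olds enter the middle-school never-smoker stock.

Transitions are first-order hazards modulated by multiplicative
feedback effects, each normalized to 1 at 1992 reference conditions:

- **Social pressure** (reinforcing): the blend
  `SP = w·peer_prevalence + (1−w)·parental_prevalence` scales
  initiation, progression and experimenter relapse as `(SP/SP_ref)^s`.
- **Secondhand smoke → nicotine dependence** (reinforcing): the same
  exposure blend linearly boosts initiation, `1 + s_shs·SP`.
- **Nicotine dependence** (reinforcing): relative monthly smoking
  quantity `Q/Q_ref` attenuates cessation as `(Q/Q_ref)^(−s_nd)` and
  fuels smoker relapse as `(Q/Q_ref)^(s_nd)`, with
  `Q = Q_ref·(P/P_ref)^ε_q` and monthly quantity defined as days
  smoked per month × cigarettes per day.
- **Price**: the income-adjusted price `P = (retail + tax)/income`
  moves quantity (and through it initiation/progression) and raises
  cessation directly as `(P/P_ref)^ε_cess`.
- **Availability**: perceived availability `A = 1 − retailer
  compliance` scales initiation and progression as `(A/A_ref)^s_avail`.
- **Risk perception** (balancing): prevalence smoothed with a
  first-order delay suppresses initiation once it exceeds its
  reference; comprehensive-program funding above the CDC-recommended
  $9.80/capita adds to both perceived risk and marketing suppression.
- **Marketing**: a baseline index, cut by the 1998 Master Settlement
  Agreement's advertising restrictions, multiplies initiation.

Integration is explicit Euler on a fixed grid (default dt = ⅛ year),
with classical RK4 available as a reference method and convergence
tests in the suite.

Three policy levers are applied as step changes in 2015 and evaluated
as the percent reduction in averaged 2032 prevalence relative to the
no-policy base run: raising the $0.44/pack excise tax to $1.44 or
$2.20, doubling program funding to $20/capita, and raising retailer
compliance to 95%.

## Worked example

```bash
smokesim synth --out data --seed 3          # synthetic env + historical CSVs
smokesim policy-compare --env data/env.csv --out results
```

prints

```
scenario         prev 2032  reduction
ALL_COMBINED        0.0424      22.4%
TAX_220             0.0452      17.3%
TAX_144             0.0488      10.8%
FUNDING_20          0.0522       4.6%
COMPLIANCE_95       0.0535       2.2%
```

Reading: under the no-policy base run the averaged past-30-day smoking
rate falls to 5.5% by 2032 on its own; the $2.20 tax cuts a further
17.3% off that level, the two weaker levers 4.6% and 2.2%, and all
three together 22.4% — within 1.7 percentage points of the sum of the
individual effects, i.e. the policies combine nearly additively. The
ranking (tax ≫ program funding > retailer compliance) is the model's
robust conclusion; the absolute percentages depend on the soft-variable
calibration and should be read as indicative.

The same pipeline is available as library calls
(`smokesim.run_policy_comparison`, `smokesim.calibrate`,
`smokesim.sensitivity_sweep`, ...); see `docs/methods.md` for the
model's assumptions, parameters and limitations.

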
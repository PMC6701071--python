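# Methods

This note documents the model, its parameters, the synthetic data, the
numerical choices, and the design decisions taken where the design was
genuinely open. Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Model structure and assumptions

The model is a deterministic compartmental ("stock-and-flow") system
in continuous time, 1992–2032. Two school-age cohorts — middle school
(ages 11–14) and high school (15–18) — are run in parallel; each holds
five mutually exclusive stocks (never smokers, current experimenters,
former experimenters, current smokers, ex-smokers) whose sum is the
cohort population. Assumptions worth making explicit:

- **Aging chain.** Each cohort spans 4 years and is treated as
  well-mixed: every stock graduates at 1/(4 yr) — the standard SD
  approximation of a 4-year cohort, which smears individual ages.
  All entrants are never-smokers (entrants are ~11-year-olds).
  Mortality is ignored (negligible at these ages over this horizon).
- **One-way lifetime status.** The 100-cigarettes-lifetime line is
  absorbing: smoker-side stocks never flow back to experimenter-side
  stocks. This is asserted on the flow graph in the tests.
- **Feedback as normalized multipliers.** No equations for the
  behavioral effects are available in the source literature for this
  setting, so all effects are multiplicative modifiers on base
  hazards, equal to 1 at 1992 reference conditions —
  constant-elasticity (power) forms for continuous drivers (price,
  quantity, social pressure, availability) and linear gains for
  bounded indices (secondhand-smoke exposure, funding excess). This
  makes every loop individually switch-off-able and the calibration
  identifiable.
- **Secondhand-smoke exposure** reuses the peer/parent prevalence
  blend of the social-pressure loop rather than introducing a separate
  exposure submodel: one index keeps the model minimal.
- **Nicotine dependence** is represented by relative smoking quantity
  Q/Q_ref rather than a separate stock; quantity is its only
  behavioral correlate in the model, entering cessation (−) and
  relapse (+).
- **Risk perception** is a single first-order smoothing stock of the
  *averaged* prevalence (time constant `tau_risk`), suppressing
  initiation once it exceeds its reference level. Smoothing is the
  only within-step memory; all other auxiliaries are memoryless.
- **Parental smoking** is exogenous. The 40-year horizon barely spans
  one generation, so endogenizing the parent loop would be weakly
  constrained; the series is an input instead.
- **Policy channels.** Tax: full pass-through to consumer price
  (pass-through 1.0), acting through quantity on initiation and
  progression and through price on cessation. Funding: split between
  marketing suppression (`s_fund`) and risk perception
  (`s_fund_risk`), default equal weight. Compliance: availability
  channel only.

## Parameters

Units and defaults live in `BehaviorParams`; the ones that matter most:

| parameter | meaning | default | unit |
|---|---|---|---|
| `h_init` | base initiation hazard | 0.10 | /yr |
| `h_prog` | experimenter → smoker progression | 0.30 | /yr |
| `h_quit_exp` | experimenters quitting | 0.40 | /yr |
| `h_quit_smk` | smoker cessation | 0.12 | /yr |
| `h_rel_exp`, `h_rel_smk` | relapse hazards | 0.15, 0.05 | /yr |
| `s_social` | social-pressure elasticity | 1.0 | – |
| `w_peer` | peer weight in the pressure blend | 0.7 | – |
| `eps_q` | price elasticity of quantity | −0.8 | – |
| `s_q_init`, `s_q_prog` | quantity → initiation/progression | 0.7 | – |
| `eps_cess` | price elasticity of cessation | 0.4 | – |
| `s_nd` | dependence attenuation/relapse gain | 0.3 | – |
| `s_avail` | availability elasticity | 0.007 | – |
| `s_risk` | risk-perception gain | 6.0 | – |
| `tau_risk` | risk smoothing delay | 3.0 | yr |
| `m_msa` | MSA marketing cut (1998) | 0.40 | fraction |
| `s_fund`, `s_fund_risk` | funding gains | 0.013 each | – |

Reference conditions anchor all multipliers at 1 in 1992: income-
adjusted price $4.00/pack ($3.56 retail + $0.44 tax), quantity 100
cigarettes/month, social-pressure blends 0.159 (middle) / 0.215
(high), retailer compliance 73% (middle) / 78% (high), program funding
$9.80/capita. The compliance references follow the Methods-style
assignment (higher compliance toward high-school buyers); the
literature on this point is internally inconsistent, so both values
are plain config fields.

**How the defaults were set.** Base hazards and feedback gains are
"soft variables": no direct measurements exist at this resolution.
They were calibrated, once, so that the default base run reproduces
the documented qualitative history — a rise from 16% in 1992 to a
~22% peak around 1997, then a monotone decline through 2032 — and so
that the three policy levers rank and scale sensibly (tax strongest,
funding intermediate, compliance weakest). One consequence is worth
stating honestly: because every channel is a multiplicative modifier,
percent reductions of simultaneous policies combine multiplicatively,
`1 − Π(1 − r_i)`, so the combined-minus-sum gap is about
Σ r_i·r_j. Near-exact additivity of large effects (30%+ from a tax
alone) is therefore structurally impossible in this functional family;
the default calibration keeps individual effects moderate
(TAX_220 ≈ 17%), which keeps the interaction below 2 percentage
points and the "policies are nearly additive" conclusion faithful.
Larger published effect sizes from graphical SD implementations are
not reproducible without their (unpublished) equation set.

Initial 1992 stocks decompose observed prevalence with calibratable
fractions: 70% of current users are experimenters, and the former/ex
pools start equal to their current counterparts (a 50/50
current-vs-former split on each side of the 100-cigarette line).

## Synthetic data

The generators in `smokesim.synthetic` replace survey and economic
inputs so the pipeline needs no downloads:

- **Target series**: logistic rise from `p_1992 = 0.16` to
  `p_peak = 0.22` (midpoint 2.5 yr before the 1997 peak, 1-yr width)
  times `exp(−0.07·(year − peak))` after the peak, with optional
  truncated Gaussian noise. These numbers are illustrative stand-ins
  that mirror the *shape* of the national youth-smoking trend, not
  Monitoring-the-Future values.
- **Environment**: retail price growing 3%/yr from $3.56, income
  index 2%/yr, flat $0.44 tax, 8 000 entrants/yr, parental prevalence
  declining linearly from 0.25, funding flat at $9.80/capita.
- **Observations**: the model's own prevalence at integer years plus
  seeded Gaussian noise truncated to [0, 1] — additive homoscedastic
  noise, exactly the error model the least-squares calibration
  assumes. Binomial survey-sampling noise, survey weighting, and
  state-level small-area structure are *not* emulated, so passing
  recovery tests demonstrates internal consistency of the estimator,
  not robustness to real survey error.

## Calibration and validation

- **Fit criterion**: unweighted SSE between simulated and observed
  prevalence (averaged or per cohort, per the `cohort` column);
  bounded nonlinear least squares (`scipy.optimize.least_squares`,
  trust-region reflective) from 10 seeded uniform random starts
  (default seed 20190820). Point bounds short-circuit without
  optimization; non-convergence of every start raises rather than
  returning silently.
- **Parameter-recovery study** (`parameter_recovery_study`): refits
  {`h_init`, `h_quit_exp`, `h_quit_smk`, `s_social`, `m_msa`} — the
  quintet with the best joint Fisher-information conditioning — from
  cohort-resolved noisy observations (sd 0.005) over the full grid,
  five replicates, bounds ±40% around truth, summarized as
  per-parameter mean absolute relative error. Averaged-only
  observations leave several directions on a likelihood ridge; the
  cohort split is what makes five parameters jointly identifiable.
- **Sensitivity**: one-at-a-time sweeps of the soft parameters (±20%
  relative; peer weight ±0.1 absolute; 5 points each), recording the
  maximum 2032 level change and whether the behavior mode survives.
  "Behavior mode preserved" is operationalized as: peak year shifts
  ≤ 2 years *and* the sign pattern of 3-point-median-smoothed yearly
  differences is unchanged (differences below 1e-4 count as flat).
  Base hazards are excluded from the default catalog because the
  historical fit identifies them directly.

## Numerics

- Explicit Euler, default dt = 0.125 yr; the suite checks that halving
  dt moves no 2032 stock by more than 0.5%, that Euler converges to
  analytic exponentials at the expected first-order rate, and that RK4
  (the built-in reference method) matches a matrix-exponential closed
  form to 0.1% over the full horizon. With hazards ≤ 0.1/yr, Euler's
  truncation error over a decade at dt = 1/64 stays under 0.1% (the
  error scales as T·k²·dt/2, so the same tolerance over 40 years would
  require dt ≈ 1/200).
- Flows are non-negative by construction (hazard × stock); a step that
  would drive a stock negative raises `IntegrationUnderflowError`
  rather than clamping, because negativity indicates a malformed
  equation or an oversized step, not a meaningful state. A jitter
  band of 1e-9 absorbs float noise at zero.
- Exogenous series: linear interpolation between yearly entries,
  constant extrapolation beyond endpoints; policy steps are
  left-closed (the "after" value applies from the start of the switch
  year, matching implementation at the start of 2015).
- Availability is floored at 0.01 so the power form stays finite as
  compliance → 1. Shape metrics break peak ties toward the earliest
  year.

## Known limitations

- Soft-variable defaults are one defensible calibration, not
  estimates with uncertainty; only the ranking and sign conclusions
  are robust across the swept ranges.
- Other tobacco products and e-cigarettes are out of scope (the hook
  exists only as the fixed dependence channel); so are demographic
  covariates, cost-effectiveness, and stochastic/agent-based dynamics.
- The two-cohort aging chain blurs within-cohort age structure;
  graduation is exponential rather than a fixed 4-year delay.
- The risk-perception proxy (smoothed prevalence) stands in for the
  unmodeled chain prevalence → smoking-attributable disease →
  perceived risk.
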
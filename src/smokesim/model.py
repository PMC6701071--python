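"""Two-cohort aging-chain model of adolescent smoking behavior.

Middle-school (ages 11-14) and high-school (ages 15-18) cohorts are run
in parallel.  Within each cohort five mutually exclusive stocks track
lifetime/current smoking status: never-smokers, current experimenters
(< 100 cigarettes lifetime, smoked in the past 30 days), former
experimenters, current smokers (>= 100 cigarettes lifetime), and
ex-smokers.  Transitions are initiation, progression, cessation and
relapse; once someone crosses the 100-cigarette line they can never
return to an experimenter stock.  Each cohort spans four years, so
every stock ages into the next cohort (or out of the model) at 1/4 of
its level per year; new 11-year-olds enter the middle-school
never-smoker stock.

Behavioral feedback enters as multiplicative modifiers on base hazards,
each normalized to 1 at 1992 reference conditions:

* social pressure (reinforcing): a peer/parent prevalence blend raised
  to an elasticity scales initiation, progression and experimenter
  relapse;
* secondhand smoke -> nicotine dependence (reinforcing): the same
  exposure blend linearly boosts initiation;
* nicotine dependence (reinforcing): relative smoking quantity Q/Q_ref
  attenuates cessation and fuels relapse;
* price: income-adjusted cigarette price moves monthly smoking quantity
  (constant elasticity), which feeds initiation/progression, and raises
  cessation directly;
* availability: retailer non-compliance sets perceived availability,
  scaling initiation and progression;
* risk perception (balancing): smoothed prevalence above its reference
  suppresses initiation; program funding above the CDC-recommended
  level adds to both perceived risk and marketing suppression;
* marketing: a baseline index cut by the 1998 Master Settlement
  Agreement and by program funding, multiplying initiation.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, fields, replace
from typing import Callable, Mapping

from .engine import (
    EXTERNAL,
    FlowValue,
    MissingInputError,
    ModelSpec,
    TimeSeries,
    step_input,
)

__all__ = [
    "Cohort",
    "STATES",
    "BehaviorParams",
    "EnvInputs",
    "InitialConditions",
    "availability_multiplier",
    "averaged_prevalence",
    "build_model",
    "cohort_population",
    "compute_flows",
    "compute_multipliers",
    "marketing_index",
    "monthly_smoking_quantity",
    "quantity_and_price_multipliers",
    "real_price",
    "risk_perception_multiplier",
    "risk_perception_state",
    "shs_dependence_multiplier",
    "simulate",
    "smoking_prevalence",
    "social_pressure_multiplier",
    "stock_name",
]


class Cohort(enum.Enum):
    """School-level age band; each spans four years."""

    MIDDLE = "middle"
    HIGH = "high"

    @property
    def span(self) -> float:
        return 4.0


#: The five mutually exclusive smoking states, in aging-chain order.
STATES = (
    "never",
    "current_experimenters",
    "former_experimenters",
    "current_smokers",
    "ex_smokers",
)

#: Name of the risk-perception smoothing stock (smoothed averaged prevalence).
RISK_STOCK = "perceived_prevalence"


def stock_name(state: str, cohort: Cohort) -> str:
    return f"{state}_{cohort.value}"


@dataclass(frozen=True)
class BehaviorParams:
    """Base hazards, feedback gains and reference conditions.

    Hazards are per year; elasticities and gains are dimensionless.
    Defaults are the package's calibrated base parameterization for the
    North Dakota 1992-2032 study window (soft variables set by fitting
    the historical prevalence shape and the documented policy-response
    magnitudes; see docs/methods.md).
    """

    # base hazards (/yr)
    h_init: float = 0.10
    h_prog: float = 0.30
    h_quit_exp: float = 0.40
    h_quit_smk: float = 0.12
    h_rel_exp: float = 0.15
    h_rel_smk: float = 0.05
    # feedback gains / elasticities
    s_social: float = 1.00  # social-pressure elasticity on initiation etc.
    s_shs: float = 0.50  # secondhand-smoke -> dependence initiation gain
    s_avail: float = 0.007  # perceived-availability elasticity
    s_risk: float = 6.0  # risk-perception gain on initiation
    eps_q: float = -0.80  # price elasticity of smoking quantity (<= 0)
    s_q_init: float = 0.70  # quantity -> initiation elasticity
    s_q_prog: float = 0.70  # quantity -> progression elasticity
    eps_cess: float = 0.40  # price elasticity of cessation (>= 0)
    s_nd: float = 0.30  # dependence (quantity) attenuation of cessation
    w_peer: float = 0.70  # peer weight in the social-pressure blend
    tau_risk: float = 3.0  # risk-perception smoothing delay (yr)
    m_msa: float = 0.40  # marketing cut at the 1998 MSA (fraction)
    s_fund: float = 0.013  # funding -> marketing suppression gain
    s_fund_risk: float = 0.013  # funding -> risk-perception gain
    m0: float = 1.0  # pre-MSA marketing baseline index
    # reference (1992) conditions anchoring the multipliers at 1
    p_ref: float = 4.00  # income-adjusted total price, USD/pack
    q_ref: float = 100.0  # monthly smoking quantity, cigarettes/month
    sp_ref_middle: float = 0.159  # social-pressure blend, MIDDLE
    sp_ref_high: float = 0.215  # social-pressure blend, HIGH
    compliance_ref_middle: float = 0.73
    compliance_ref_high: float = 0.78
    f_ref: float = 9.80  # CDC-recommended program funding, USD/capita
    risk_ref: float = 0.16  # reference smoothed averaged prevalence

    def __post_init__(self) -> None:
        for name in (
            "h_init",
            "h_prog",
            "h_quit_exp",
            "h_quit_smk",
            "h_rel_exp",
            "h_rel_smk",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"hazard {name} must be >= 0")
        if not 0.0 <= self.w_peer <= 1.0:
            raise ValueError("w_peer must be in [0, 1]")
        if not 0.0 <= self.m_msa <= 1.0:
            raise ValueError("m_msa must be in [0, 1]")
        if self.eps_q > 0:
            raise ValueError("eps_q (price elasticity of quantity) must be <= 0")
        if self.eps_cess < 0:
            raise ValueError("eps_cess must be >= 0")
        if self.tau_risk <= 0:
            raise ValueError("tau_risk must be positive")
        for name in ("p_ref", "q_ref", "sp_ref_middle", "sp_ref_high", "f_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"reference {name} must be positive")

    def sp_ref(self, cohort: Cohort) -> float:
        return self.sp_ref_middle if cohort is Cohort.MIDDLE else self.sp_ref_high

    def compliance_ref(self, cohort: Cohort) -> float:
        return (
            self.compliance_ref_middle
            if cohort is Cohort.MIDDLE
            else self.compliance_ref_high
        )

    def with_values(self, **updates: float) -> "BehaviorParams":
        return replace(self, **updates)

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


SeriesLike = Callable[[float], float]


def _as_series(value) -> SeriesLike:
    if value is None:
        raise MissingInputError("required exogenous series is missing")
    if callable(value):
        return value
    return TimeSeries(value)


@dataclass
class EnvInputs:
    """Exogenous environment of the model, each entry callable at any year.

    Scalars and year->value mappings are accepted and wrapped in
    :class:`~smokesim.engine.TimeSeries`; policy overrides wrap entries
    in :class:`~smokesim.engine.StepSeries`.
    """

    retail_price: SeriesLike  # pre-tax price, USD/pack
    excise_tax: SeriesLike  # USD/pack
    income_index: SeriesLike  # dimensionless, 1 at 1992
    entry_rate: SeriesLike  # persons/yr entering MIDDLE
    parental_prevalence: SeriesLike  # fraction
    funding_per_capita: SeriesLike  # USD/capita
    compliance_middle: SeriesLike = field(default_factory=lambda: TimeSeries(0.73))
    compliance_high: SeriesLike = field(default_factory=lambda: TimeSeries(0.78))
    msa_year: float = 1998.0

    def __post_init__(self) -> None:
        for name in (
            "retail_price",
            "excise_tax",
            "income_index",
            "entry_rate",
            "parental_prevalence",
            "funding_per_capita",
            "compliance_middle",
            "compliance_high",
        ):
            setattr(self, name, _as_series(getattr(self, name)))

    def compliance(self, cohort: Cohort) -> SeriesLike:
        return self.compliance_middle if cohort is Cohort.MIDDLE else self.compliance_high

    def copy(self) -> "EnvInputs":
        return EnvInputs(
            retail_price=self.retail_price,
            excise_tax=self.excise_tax,
            income_index=self.income_index,
            entry_rate=self.entry_rate,
            parental_prevalence=self.parental_prevalence,
            funding_per_capita=self.funding_per_capita,
            compliance_middle=self.compliance_middle,
            compliance_high=self.compliance_high,
            msa_year=self.msa_year,
        )


@dataclass(frozen=True)
class InitialConditions:
    """1992 stock decomposition.

    Only the cohort populations and past-30-day prevalences are
    observable; the split of current users between experimenters and
    smokers, and the size of the former/ex pools relative to the
    current pools, are calibratable fractions.
    """

    pop_middle: float = 32000.0
    pop_high: float = 32000.0
    prev_middle: float = 0.12
    prev_high: float = 0.20
    frac_experimenter: float = 0.70  # share of current users still experimenting
    former_per_current_exp: float = 1.0  # former experimenters per current
    ex_per_current_smk: float = 1.0  # ex-smokers per current smoker

    def to_stocks(self) -> dict[str, float]:
        stocks: dict[str, float] = {}
        for cohort, pop, prev in (
            (Cohort.MIDDLE, self.pop_middle, self.prev_middle),
            (Cohort.HIGH, self.pop_high, self.prev_high),
        ):
            current = prev * pop
            cur_exp = self.frac_experimenter * current
            cur_smk = current - cur_exp
            form_exp = self.former_per_current_exp * cur_exp
            ex_smk = self.ex_per_current_smk * cur_smk
            never = pop - (cur_exp + cur_smk + form_exp + ex_smk)
            if never < 0:
                raise ValueError(
                    f"initial decomposition exceeds cohort population ({cohort})"
                )
            stocks[stock_name("never", cohort)] = never
            stocks[stock_name("current_experimenters", cohort)] = cur_exp
            stocks[stock_name("former_experimenters", cohort)] = form_exp
            stocks[stock_name("current_smokers", cohort)] = cur_smk
            stocks[stock_name("ex_smokers", cohort)] = ex_smk
        avg = (self.prev_middle + self.prev_high) / 2.0
        stocks[RISK_STOCK] = avg  # smoothing stock starts in steady state
        return stocks


# ---------------------------------------------------------------------------
# elementary operations


def monthly_smoking_quantity(freq: float, cpd: float) -> float:
    """Cigarettes per month = days smoked per month x cigarettes per day."""
    if freq < 0 or cpd < 0:
        raise ValueError("smoking frequency and cigarettes/day must be >= 0")
    if freq > 31:
        raise ValueError(f"smoking frequency {freq} exceeds days in a month")
    return freq * cpd


def cohort_population(stocks: Mapping[str, float], cohort: Cohort) -> float:
    return sum(stocks[stock_name(s, cohort)] for s in STATES)


def smoking_prevalence(stocks: Mapping[str, float], cohort: Cohort) -> float:
    """Past-30-day smoking rate: (current experimenters + current smokers) / pop."""
    pop = cohort_population(stocks, cohort)
    if pop <= 0:
        raise ZeroDivisionError(f"cohort {cohort} has zero population")
    current = stocks[stock_name("current_experimenters", cohort)] + stocks[
        stock_name("current_smokers", cohort)
    ]
    return current / pop


def averaged_prevalence(stocks: Mapping[str, float]) -> float:
    """Unweighted mean of the middle- and high-school prevalences."""
    return (
        smoking_prevalence(stocks, Cohort.MIDDLE)
        + smoking_prevalence(stocks, Cohort.HIGH)
    ) / 2.0


def social_pressure_multiplier(
    peer_prev: float, parent_prev: float, params: BehaviorParams, cohort: Cohort
) -> float:
    """(SP / SP_ref)^s_social with SP = w_peer*peer + (1-w_peer)*parent."""
    sp_ref = params.sp_ref(cohort)
    if sp_ref <= 0:
        raise ValueError("SP_ref must be positive")
    sp = params.w_peer * peer_prev + (1.0 - params.w_peer) * parent_prev
    if sp <= 0.0:
        return 0.0 if params.s_social > 0 else 1.0
    return (sp / sp_ref) ** params.s_social


def shs_dependence_multiplier(
    peer_prev: float, parent_prev: float, params: BehaviorParams
) -> float:
    """1 + s_shs * exposure; secondhand smoke primes nicotine dependence.

    Exposure reuses the peer/parent prevalence blend of the
    social-pressure loop.
    """
    shs = params.w_peer * peer_prev + (1.0 - params.w_peer) * parent_prev
    return 1.0 + params.s_shs * shs


def real_price(retail_price: float, excise_tax: float, income_index: float) -> float:
    """Income-adjusted consumer price: (retail + tax) / income index."""
    if income_index <= 0:
        raise ValueError("income index must be positive")
    return (retail_price + excise_tax) / income_index


def quantity_and_price_multipliers(
    p_real: float, params: BehaviorParams
) -> tuple[float, float, float, float]:
    """Price channel: (Q, m_init_q, m_prog_q, m_cess_p).

    Q = Q_ref (P/P_ref)^eps_q; the quantity ratio feeds initiation and
    progression with its own elasticities; cessation responds to price
    directly.
    """
    if p_real <= 0 or params.p_ref <= 0:
        raise ValueError("prices must be positive")
    ratio = p_real / params.p_ref
    q = params.q_ref * ratio**params.eps_q
    q_rel = q / params.q_ref
    return (
        q,
        q_rel**params.s_q_init,
        q_rel**params.s_q_prog,
        ratio**params.eps_cess,
    )


AVAILABILITY_FLOOR = 0.01


def availability_multiplier(
    compliance: float, cohort: Cohort, params: BehaviorParams
) -> float:
    """(A / A_ref)^s_avail with availability A = 1 - retailer compliance.

    Availability is floored at 0.01 so the power form stays finite as
    compliance approaches 1.
    """
    if not 0.0 <= compliance <= 1.0:
        raise ValueError(f"compliance must be in [0, 1], got {compliance}")
    a = max(AVAILABILITY_FLOOR, 1.0 - compliance)
    a_ref = max(AVAILABILITY_FLOOR, 1.0 - params.compliance_ref(cohort))
    return (a / a_ref) ** params.s_avail


def risk_perception_state(
    prev_smoothed: float, current_prev: float, tau_risk: float
) -> float:
    """d(smoothed prevalence)/dt for first-order exponential smoothing."""
    if tau_risk <= 0:
        raise ValueError("tau_risk must be positive")
    return (current_prev - prev_smoothed) / tau_risk


def risk_perception_multiplier(
    prev_smoothed: float, funding_per_capita: float, params: BehaviorParams
) -> float:
    """Initiation suppression from perceived risk and program funding.

    1 / (1 + s_risk * max(0, smoothed - risk_ref)
           + s_fund_risk * max(0, funding/F_ref - 1));
    equals 1 at reference conditions, falls toward 0 as perceived risk
    or funding rise above reference.
    """
    if prev_smoothed < 0 or funding_per_capita < 0:
        raise ValueError("risk-perception inputs must be >= 0")
    excess_risk = max(0.0, prev_smoothed - params.risk_ref)
    excess_fund = max(0.0, funding_per_capita / params.f_ref - 1.0)
    return 1.0 / (1.0 + params.s_risk * excess_risk + params.s_fund_risk * excess_fund)


def marketing_index(
    t: float, funding_per_capita: float, params: BehaviorParams, env: EnvInputs
) -> float:
    """Tobacco-marketing index on the social channel of initiation.

    Baseline M0, stepped down by the Master Settlement Agreement's ad
    restrictions and further suppressed by program funding above the
    reference level.
    """
    msa_factor = step_input(t, env.msa_year, 1.0, 1.0 - params.m_msa)
    excess_fund = max(0.0, funding_per_capita / params.f_ref - 1.0)
    fund_factor = max(0.0, 1.0 - params.s_fund * excess_fund)
    return params.m0 * msa_factor * fund_factor


# ---------------------------------------------------------------------------
# model assembly


def compute_multipliers(
    t: float,
    stocks: Mapping[str, float],
    params: BehaviorParams,
    env: EnvInputs,
) -> dict[str, float]:
    """Evaluate every auxiliary (prevalences, price channel, multipliers)."""
    parent = env.parental_prevalence(t)
    funding = env.funding_per_capita(t)
    p_real = real_price(env.retail_price(t), env.excise_tax(t), env.income_index(t))
    q, m_init_q, m_prog_q, m_cess_p = quantity_and_price_multipliers(p_real, params)
    q_rel = q / params.q_ref
    m_risk = risk_perception_multiplier(stocks[RISK_STOCK], funding, params)
    mkt = marketing_index(t, funding, params, env)

    aux: dict[str, float] = {
        "parental_prevalence": parent,
        "funding_per_capita": funding,
        "real_price": p_real,
        "monthly_quantity": q,
        "quantity_ratio": q_rel,
        "m_init_q": m_init_q,
        "m_prog_q": m_prog_q,
        "m_cess_p": m_cess_p,
        "m_risk": m_risk,
        "marketing": mkt,
        "prev_smoothed": stocks[RISK_STOCK],
    }
    for cohort in Cohort:
        prev = smoking_prevalence(stocks, cohort)
        aux[f"prev_{cohort.value}"] = prev
        aux[f"m_social_{cohort.value}"] = social_pressure_multiplier(
            prev, parent, params, cohort
        )
        aux[f"m_shs_{cohort.value}"] = shs_dependence_multiplier(prev, parent, params)
        aux[f"m_avail_{cohort.value}"] = availability_multiplier(
            env.compliance(cohort)(t), cohort, params
        )
    aux["prev_avg"] = (aux["prev_middle"] + aux["prev_high"]) / 2.0
    return aux


def compute_flows(
    stocks: Mapping[str, float],
    multipliers: Mapping[str, float],
    params: BehaviorParams,
    env: EnvInputs,
    t: float,
) -> list[FlowValue]:
    """All flow rates: behavioral transitions, aging chain, entry/exit, smoothing."""
    flows: list[FlowValue] = []
    q_rel = multipliers["quantity_ratio"]
    dep_cess = q_rel ** (-params.s_nd)  # dependence attenuates cessation
    dep_rel = q_rel**params.s_nd  # and fuels smoker relapse

    for cohort in Cohort:
        c = cohort.value
        never = stocks[stock_name("never", cohort)]
        cur_exp = stocks[stock_name("current_experimenters", cohort)]
        form_exp = stocks[stock_name("former_experimenters", cohort)]
        cur_smk = stocks[stock_name("current_smokers", cohort)]
        ex_smk = stocks[stock_name("ex_smokers", cohort)]
        m_social = multipliers[f"m_social_{c}"]
        m_shs = multipliers[f"m_shs_{c}"]
        m_avail = multipliers[f"m_avail_{c}"]

        initiation = (
            never
            * params.h_init
            * m_social
            * m_shs
            * m_avail
            * multipliers["m_risk"]
            * multipliers["m_init_q"]
            * multipliers["marketing"]
        )
        flows.append(
            FlowValue(
                f"initiation_{c}",
                stock_name("never", cohort),
                stock_name("current_experimenters", cohort),
                initiation,
            )
        )
        flows.append(
            FlowValue(
                f"quit_experimenting_{c}",
                stock_name("current_experimenters", cohort),
                stock_name("former_experimenters", cohort),
                cur_exp * params.h_quit_exp,
            )
        )
        flows.append(
            FlowValue(
                f"experimenter_relapse_{c}",
                stock_name("former_experimenters", cohort),
                stock_name("current_experimenters", cohort),
                form_exp * params.h_rel_exp * m_social,
            )
        )
        flows.append(
            FlowValue(
                f"progression_{c}",
                stock_name("current_experimenters", cohort),
                stock_name("current_smokers", cohort),
                cur_exp
                * params.h_prog
                * m_social
                * m_avail
                * multipliers["m_prog_q"],
            )
        )
        flows.append(
            FlowValue(
                f"cessation_{c}",
                stock_name("current_smokers", cohort),
                stock_name("ex_smokers", cohort),
                cur_smk * params.h_quit_smk * multipliers["m_cess_p"] * dep_cess,
            )
        )
        flows.append(
            FlowValue(
                f"smoker_relapse_{c}",
                stock_name("ex_smokers", cohort),
                stock_name("current_smokers", cohort),
                ex_smk * params.h_rel_smk * dep_rel,
            )
        )

    # aging chain: every MIDDLE stock graduates to HIGH at 1/span per year;
    # every HIGH stock leaves the modeled age range at the same fractional rate
    for state in STATES:
        mid = stock_name(state, Cohort.MIDDLE)
        high = stock_name(state, Cohort.HIGH)
        flows.append(
            FlowValue(
                f"graduate_{state}", mid, high, stocks[mid] / Cohort.MIDDLE.span
            )
        )
        flows.append(
            FlowValue(
                f"exit_{state}", high, EXTERNAL, stocks[high] / Cohort.HIGH.span
            )
        )
    flows.append(
        FlowValue(
            "entry",
            EXTERNAL,
            stock_name("never", Cohort.MIDDLE),
            env.entry_rate(t),
        )
    )

    # first-order smoothing of averaged prevalence (risk-perception memory),
    # expressed as a non-negative inflow/outflow pair
    flows.append(
        FlowValue(
            "risk_smoothing_in",
            EXTERNAL,
            RISK_STOCK,
            multipliers["prev_avg"] / params.tau_risk,
        )
    )
    flows.append(
        FlowValue(
            "risk_smoothing_out",
            RISK_STOCK,
            EXTERNAL,
            stocks[RISK_STOCK] / params.tau_risk,
        )
    )
    return flows


def build_model(
    params: BehaviorParams,
    env: EnvInputs,
    initial: InitialConditions | Mapping[str, float] | None = None,
) -> ModelSpec:
    """Wire parameters, environment and initial stocks into an engine model."""
    if initial is None:
        initial = InitialConditions()
    stocks0 = initial.to_stocks() if isinstance(initial, InitialConditions) else dict(initial)
    expected = {stock_name(s, c) for s in STATES for c in Cohort} | {RISK_STOCK}
    missing = expected - set(stocks0)
    if missing:
        raise ValueError(f"initial stocks missing: {sorted(missing)}")

    def aux_fn(t: float, stocks: Mapping[str, float]) -> dict[str, float]:
        return compute_multipliers(t, stocks, params, env)

    def flow_fn(
        t: float, stocks: Mapping[str, float], aux: Mapping[str, float]
    ) -> list[FlowValue]:
        return compute_flows(stocks, aux, params, env, t)

    return ModelSpec(initial=stocks0, auxiliaries=aux_fn, flows=flow_fn)


def simulate(
    params: BehaviorParams,
    env: EnvInputs,
    initial: InitialConditions | Mapping[str, float] | None = None,
    grid=None,
    method: str = "euler",
):
    """Build and run the smoking model; returns a Trajectory."""
    from .engine import TimeGrid, run_simulation

    if grid is None:
        grid = TimeGrid()
    return run_simulation(build_model(params, env, initial), grid, method=method)
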
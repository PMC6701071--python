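"""Tobacco-control policy levers, the named scenario catalog, and outcomes.

Three levers are modeled, each applied as a step change in simulation
year 2015: raising the excise tax (acting through smoking quantity on
initiation/progression and through price on cessation), raising
comprehensive-program funding (acting through marketing suppression
and risk perception), and raising retailer compliance (acting through
perceived availability).  Outcomes are percent reductions in the
averaged past-30-day smoking rate at 2032 relative to the no-policy
base run.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .engine import StepSeries, TimeGrid, Trajectory
from .model import BehaviorParams, EnvInputs, InitialConditions, simulate

__all__ = [
    "PolicyOutcome",
    "PolicyScenario",
    "apply_scenario",
    "percent_reduction",
    "run_policy_comparison",
    "scenario_catalog",
]

#: Marker for a lever a scenario leaves at its base-case value.
UNCHANGED = None


@dataclass(frozen=True)
class PolicyScenario:
    """One policy experiment: levers stepped at ``start_year``; None = unchanged."""

    name: str
    tax_per_pack: float | None = UNCHANGED
    funding_per_capita: float | None = UNCHANGED
    compliance_middle: float | None = UNCHANGED
    compliance_high: float | None = UNCHANGED
    start_year: float = 2015.0

    def __post_init__(self) -> None:
        if self.tax_per_pack is not None and self.tax_per_pack < 0:
            raise ValueError("tax must be >= 0")
        if self.funding_per_capita is not None and self.funding_per_capita < 0:
            raise ValueError("funding must be >= 0")
        for c in (self.compliance_middle, self.compliance_high):
            if c is not None and not 0.0 <= c < 1.0:
                raise ValueError("compliance must be in [0, 1)")

    @property
    def is_base(self) -> bool:
        return (
            self.tax_per_pack is None
            and self.funding_per_capita is None
            and self.compliance_middle is None
            and self.compliance_high is None
        )


@dataclass(frozen=True)
class PolicyOutcome:
    """Averaged 2032 prevalence under a scenario versus the base run."""

    scenario: str
    prevalence_2032: float
    base_prevalence_2032: float

    @property
    def pct_reduction(self) -> float:
        return 100.0 * (self.base_prevalence_2032 - self.prevalence_2032) / (
            self.base_prevalence_2032
        )


def scenario_catalog() -> dict[str, PolicyScenario]:
    """The study's six named runs.

    BASE keeps the $0.44/pack tax (unchanged since 1993), $9.80/capita
    funding and 73%/78% compliance; TAX_144 and TAX_220 are the two
    excise-tax proposals; FUNDING_20 doubles program funding;
    COMPLIANCE_95 raises both cohorts' retailer compliance to 95%;
    ALL_COMBINED applies the higher tax plus funding plus compliance.
    """
    scenarios = [
        PolicyScenario("BASE"),
        PolicyScenario("TAX_144", tax_per_pack=1.44),
        PolicyScenario("TAX_220", tax_per_pack=2.20),
        PolicyScenario("FUNDING_20", funding_per_capita=20.0),
        PolicyScenario("COMPLIANCE_95", compliance_middle=0.95, compliance_high=0.95),
        PolicyScenario(
            "ALL_COMBINED",
            tax_per_pack=2.20,
            funding_per_capita=20.0,
            compliance_middle=0.95,
            compliance_high=0.95,
        ),
    ]
    return {s.name: s for s in scenarios}


def apply_scenario(
    env: EnvInputs,
    params: BehaviorParams,
    scenario: PolicyScenario,
    grid: TimeGrid | None = None,
) -> tuple[EnvInputs, BehaviorParams]:
    """Impose a scenario's step changes on the environment.

    Only the targeted series are wrapped in step overrides; BASE
    returns the inputs untouched.  Behavioral parameters are returned
    unchanged (all three levers act through the environment).
    """
    if grid is not None and not (grid.t_start <= scenario.start_year <= grid.t_end):
        raise ValueError(
            f"scenario start year {scenario.start_year} outside the grid "
            f"[{grid.t_start}, {grid.t_end}]"
        )
    if scenario.is_base:
        return env, params
    new_env = env.copy()
    t0 = scenario.start_year
    if scenario.tax_per_pack is not None:
        new_env.excise_tax = StepSeries(env.excise_tax, t0, scenario.tax_per_pack)
    if scenario.funding_per_capita is not None:
        new_env.funding_per_capita = StepSeries(
            env.funding_per_capita, t0, scenario.funding_per_capita
        )
    if scenario.compliance_middle is not None:
        new_env.compliance_middle = StepSeries(
            env.compliance_middle, t0, scenario.compliance_middle
        )
    if scenario.compliance_high is not None:
        new_env.compliance_high = StepSeries(
            env.compliance_high, t0, scenario.compliance_high
        )
    return new_env, params


def percent_reduction(
    base_traj: Trajectory, policy_traj: Trajectory, eval_year: float = 2032.0
) -> float:
    """100 x (base - policy) / base averaged prevalence at ``eval_year``."""
    p_base = base_traj.at("prev_avg", eval_year)
    p_policy = policy_traj.at("prev_avg", eval_year)
    if p_base <= 0:
        raise ZeroDivisionError("base prevalence is zero at the evaluation year")
    return 100.0 * (p_base - p_policy) / p_base


def run_policy_comparison(
    params: BehaviorParams,
    env: EnvInputs,
    initial: InitialConditions | None = None,
    grid: TimeGrid | None = None,
    scenarios: Iterable[PolicyScenario] | Mapping[str, PolicyScenario] | None = None,
    eval_year: float = 2032.0,
) -> list[PolicyOutcome]:
    """One base run plus one run per non-base scenario.

    Returns outcomes sorted by percent reduction, descending.
    """
    if grid is None:
        grid = TimeGrid()
    if scenarios is None:
        scenarios = scenario_catalog()
    if isinstance(scenarios, Mapping):
        scenarios = list(scenarios.values())
    base_traj = simulate(params, env, initial, grid)
    p_base = base_traj.at("prev_avg", eval_year)
    outcomes = []
    for scenario in scenarios:
        if scenario.is_base:
            continue
        s_env, s_params = apply_scenario(env, params, scenario, grid)
        traj = simulate(s_params, s_env, initial, grid)
        outcomes.append(
            PolicyOutcome(
                scenario=scenario.name,
                prevalence_2032=traj.at("prev_avg", eval_year),
                base_prevalence_2032=p_base,
            )
        )
    return sorted(outcomes, key=lambda o: o.pct_reduction, reverse=True)


def outcomes_frame(outcomes: Iterable[PolicyOutcome]) -> pd.DataFrame:
    """Outcomes as a table: scenario, prevalences, percent reduction."""
    return pd.DataFrame(
        [
            {
                "scenario": o.scenario,
                "prevalence_2032": o.prevalence_2032,
                "base_prevalence_2032": o.base_prevalence_2032,
                "pct_reduction": o.pct_reduction,
            }
            for o in outcomes
        ]
    )
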
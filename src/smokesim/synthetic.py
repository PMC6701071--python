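"""Synthetic inputs: historical-shaped prevalence targets and environment series.

The real study calibrated against Monitoring the Future survey rates
(1992-2014) and North Dakota economic series; neither is bundled here.
These generators emit stand-ins with the documented qualitative
structure — a rise from 1992 to a mid-1990s peak followed by a monotone
decline, exponentially growing price and income, a flat $0.44/pack
excise tax — so the whole pipeline (simulate, calibrate, run policy
experiments) is exercisable offline from a single seed.  Default shape
numbers are illustrative, not survey values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .engine import TimeGrid
from .model import BehaviorParams, EnvInputs, InitialConditions, simulate

__all__ = [
    "EnvShapeParams",
    "TargetShapeParams",
    "generate_env_inputs",
    "generate_observations_from_model",
    "generate_target_series",
]


@dataclass(frozen=True)
class TargetShapeParams:
    """Shape of the synthetic historical prevalence curve.

    Logistic rise from ``p_1992`` toward ``p_peak`` (centered shortly
    before ``peak_year``), multiplied by exponential decay at
    ``decline_rate`` after the peak; optional truncated Gaussian noise.
    """

    p_1992: float = 0.16
    p_peak: float = 0.22
    peak_year: float = 1997.0
    decline_rate: float = 0.07
    noise_sd: float = 0.0
    seed: int = 0
    rise_width: float = 1.0  # logistic time scale, years
    center_lead: float = 2.5  # years the logistic midpoint precedes the peak

    def __post_init__(self) -> None:
        if not 0.0 < self.p_1992 <= self.p_peak < 1.0:
            raise ValueError("need 0 < p_1992 <= p_peak < 1")
        if not 1992.0 < self.peak_year < 2014.0:
            raise ValueError("peak_year must lie strictly inside 1992-2014")
        if self.decline_rate <= 0:
            raise ValueError("decline_rate must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def _target_curve(shape: TargetShapeParams, years: np.ndarray) -> np.ndarray:
    center = shape.peak_year - shape.center_lead
    logistic = 1.0 / (1.0 + np.exp(-(years - center) / shape.rise_width))
    rise = shape.p_1992 + (shape.p_peak - shape.p_1992) * logistic
    decline = np.exp(-shape.decline_rate * np.maximum(0.0, years - shape.peak_year))
    return rise * decline


def generate_target_series(
    shape: TargetShapeParams | None = None,
    years=None,
) -> pd.DataFrame:
    """Synthetic averaged past-30-day prevalence, one row per year.

    Returns a DataFrame with columns ``year``, ``cohort`` (AVERAGED)
    and ``prevalence``; deterministic when ``noise_sd`` is 0, seeded
    otherwise.
    """
    if shape is None:
        shape = TargetShapeParams()
    if years is None:
        years = np.arange(1992, 2015)
    years = np.asarray(years, dtype=float)
    prev = _target_curve(shape, years)
    if shape.noise_sd > 0:
        rng = np.random.default_rng(shape.seed)
        prev = prev + rng.normal(0.0, shape.noise_sd, size=prev.shape)
    prev = np.clip(prev, 0.0, 1.0)
    return pd.DataFrame(
        {"year": years.astype(int), "cohort": "AVERAGED", "prevalence": prev}
    )


@dataclass(frozen=True)
class EnvShapeParams:
    """Shape of the synthetic exogenous environment.

    Price and income grow exponentially, cohort entry linearly,
    parental smoking prevalence linearly (clamped to [0, 1]); the
    excise tax is held at the 1993-era $0.44/pack and program funding
    at the CDC-recommended $9.80/capita unless a policy changes them.
    """

    price_1992: float = 3.56
    price_growth: float = 0.03
    income_growth: float = 0.02
    entry_1992: float = 8000.0
    entry_growth: float = 0.0
    parent_prev_1992: float = 0.25
    parent_prev_slope: float = -0.003
    tax: float = 0.44
    funding: float = 9.80
    compliance_middle: float = 0.73
    compliance_high: float = 0.78
    seed: int = 0

    def __post_init__(self) -> None:
        if self.price_1992 <= 0 or self.entry_1992 <= 0:
            raise ValueError("price_1992 and entry_1992 must be positive")
        if not 0.0 <= self.parent_prev_1992 <= 1.0:
            raise ValueError("parent_prev_1992 must be a fraction")


def generate_env_inputs(
    shape: EnvShapeParams | None = None, grid: TimeGrid | None = None
) -> EnvInputs:
    """Yearly exogenous series covering the grid, as :class:`EnvInputs`."""
    if shape is None:
        shape = EnvShapeParams()
    if grid is None:
        grid = TimeGrid()
    years = np.arange(np.floor(grid.t_start), np.ceil(grid.t_end) + 1)
    dt_years = years - 1992.0

    parent = shape.parent_prev_1992 + shape.parent_prev_slope * dt_years
    clamped = (parent < 0.0) | (parent > 1.0)
    if clamped.mean() > 0.20:
        raise ValueError(
            "parental-prevalence slope clamps more than 20% of the horizon"
        )
    parent = np.clip(parent, 0.0, 1.0)

    def series(values: np.ndarray) -> dict[float, float]:
        return dict(zip(years.tolist(), np.asarray(values, dtype=float).tolist()))

    return EnvInputs(
        retail_price=series(shape.price_1992 * np.exp(shape.price_growth * dt_years)),
        excise_tax=series(np.full_like(years, shape.tax, dtype=float)),
        income_index=series(np.exp(shape.income_growth * dt_years)),
        entry_rate=series(shape.entry_1992 + shape.entry_growth * dt_years),
        parental_prevalence=series(parent),
        funding_per_capita=series(np.full_like(years, shape.funding, dtype=float)),
        compliance_middle=shape.compliance_middle,
        compliance_high=shape.compliance_high,
    )


def generate_observations_from_model(
    true_params: BehaviorParams,
    env: EnvInputs,
    initial: InitialConditions | None = None,
    grid: TimeGrid | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
    years=None,
    cohorts: tuple[str, ...] = ("AVERAGED",),
) -> pd.DataFrame:
    """Model-generated noisy observations for parameter-recovery studies.

    Runs the smoking model at ``true_params``, samples prevalence at
    integer years (1992-2014 by default) and adds seeded Gaussian noise
    truncated to [0, 1].  ``cohorts`` selects which series are
    observed: the default is the averaged rate; pass
    ``("MIDDLE", "HIGH")`` for cohort-resolved observations (surveys
    report the cohorts separately, and the extra resolution is what
    makes several parameters jointly identifiable).
    """
    if grid is None:
        grid = TimeGrid()
    if years is None:
        years = np.arange(1992, 2015)
    columns = {"AVERAGED": "prev_avg", "MIDDLE": "prev_middle", "HIGH": "prev_high"}
    traj = simulate(true_params, env, initial, grid)
    rng = np.random.default_rng(seed)
    frames = []
    for cohort in cohorts:
        prev = np.array([traj.at(columns[cohort], float(y)) for y in years])
        if noise_sd > 0:
            prev = prev + rng.normal(0.0, noise_sd, size=prev.shape)
        frames.append(
            pd.DataFrame(
                {
                    "year": np.asarray(years, dtype=int),
                    "cohort": cohort,
                    "prevalence": np.clip(prev, 0.0, 1.0),
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
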
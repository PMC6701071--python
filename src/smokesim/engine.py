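"""Deterministic stock-and-flow integration engine.

A model is a :class:`ModelSpec`: initial stock levels, an auxiliary
evaluator, and a flow evaluator.  :func:`run_simulation` advances the
stocks on a fixed time grid with explicit Euler (default) or classical
RK4 (reference method), recording every stock, auxiliary and flow at
every grid point.

Conventions
-----------
* Stocks are named levels (persons, or dimensionless smoothing states).
* Flows are non-negative rates between stocks or across the model
  boundary (``EXTERNAL``).  A stock that would be driven negative within
  one step raises :class:`IntegrationUnderflowError` rather than being
  clamped: in this model every outflow is hazard x stock, so negativity
  indicates a bug or a too-large step, not a meaningful state.
* Yearly exogenous series are linearly interpolated between entries and
  held constant beyond their endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

EXTERNAL = "EXTERNAL"

__all__ = [
    "EXTERNAL",
    "EmptySeriesError",
    "FlowValue",
    "IntegrationUnderflowError",
    "MissingInputError",
    "ModelSpec",
    "StepSeries",
    "TimeGrid",
    "TimeSeries",
    "Trajectory",
    "euler_step",
    "interpolate_series",
    "run_simulation",
    "step_input",
]


class IntegrationUnderflowError(RuntimeError):
    """A stock would be driven below zero within one integration step."""


class MissingInputError(KeyError):
    """An exogenous input required by the model is absent."""


class EmptySeriesError(ValueError):
    """A time series with no entries was queried."""


class FlowValue(NamedTuple):
    """A named rate moving quantity from ``source`` to ``sink`` (persons/yr)."""

    name: str
    source: str
    sink: str
    rate: float


@dataclass(frozen=True)
class TimeGrid:
    """Uniform simulation grid in calendar years.

    ``dt`` is a fraction of a year; the span must be an integer number
    of steps.
    """

    t_start: float = 1992.0
    t_end: float = 2032.0
    dt: float = 0.125

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError(f"dt must be positive, got {self.dt}")
        if self.t_start >= self.t_end:
            raise ValueError("t_start must precede t_end")
        n = (self.t_end - self.t_start) / self.dt
        if abs(n - round(n)) > 1e-9 * max(1.0, n):
            raise ValueError(
                f"({self.t_end} - {self.t_start}) / {self.dt} is not an "
                "integer number of steps"
            )

    @property
    def n_steps(self) -> int:
        return int(round((self.t_end - self.t_start) / self.dt))

    def times(self) -> np.ndarray:
        """All grid points, t_start through t_end inclusive."""
        return self.t_start + self.dt * np.arange(self.n_steps + 1)


def step_input(t: float, t_switch: float, before: float, after: float) -> float:
    """Left-closed step: ``before`` for t < t_switch, ``after`` for t >= t_switch.

    Policies implemented in a given simulation year act from the start
    of that year.
    """
    return after if t >= t_switch else before


def interpolate_series(series: Mapping[float, float], t: float) -> float:
    """Linear interpolation of a year-indexed series, constant beyond endpoints."""
    if not series:
        raise EmptySeriesError("cannot interpolate an empty series")
    years = np.array(sorted(series))
    values = np.array([series[y] for y in years], dtype=float)
    return float(np.interp(t, years, values))


class TimeSeries:
    """Year-indexed exogenous input, callable at any time.

    Accepts a scalar (constant series) or a mapping year -> value.
    Linear interpolation between entries; constant extrapolation
    outside the covered range.
    """

    def __init__(self, data: Mapping[float, float] | float | int):
        if isinstance(data, (int, float)):
            self._years = np.array([0.0])
            self._values = np.array([float(data)])
        else:
            if len(data) == 0:
                raise EmptySeriesError("time series needs at least one entry")
            years = np.array(sorted(data), dtype=float)
            self._years = years
            self._values = np.array([data[y] for y in sorted(data)], dtype=float)

    def __call__(self, t: float) -> float:
        if len(self._years) == 1:
            return float(self._values[0])
        return float(np.interp(t, self._years, self._values))

    def to_dict(self) -> dict[float, float]:
        return dict(zip(self._years.tolist(), self._values.tolist()))


class StepSeries:
    """A series overridden by a constant from ``t_switch`` onward.

    Used to impose policy step changes (tax, funding, compliance) on an
    otherwise unchanged exogenous input.
    """

    def __init__(self, base: Callable[[float], float], t_switch: float, after: float):
        self.base = base
        self.t_switch = float(t_switch)
        self.after = float(after)

    def __call__(self, t: float) -> float:
        return step_input(t, self.t_switch, self.base(t), self.after)


@dataclass
class ModelSpec:
    """Everything the engine needs: initial stocks and the step equations.

    ``auxiliaries(t, stocks)`` returns the named auxiliary values
    (multipliers, prices, prevalences) at time ``t``;
    ``flows(t, stocks, aux)`` returns the flow rates.  Evaluation order
    within a step is auxiliaries -> flows -> stock update.
    """

    initial: dict[str, float]
    auxiliaries: Callable[[float, Mapping[str, float]], dict[str, float]]
    flows: Callable[
        [float, Mapping[str, float], Mapping[str, float]], Sequence[FlowValue]
    ]


def euler_step(
    state: Mapping[str, float], flows: Sequence[FlowValue], dt: float
) -> dict[str, float]:
    """One explicit-Euler update: level += dt * (inflows - outflows)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    net = _net_rates(state, flows)
    new_state = {}
    for name, level in state.items():
        new = level + dt * net.get(name, 0.0)
        if new < 0.0:
            if new > -1e-9 * max(1.0, abs(level)):
                new = 0.0  # float jitter at zero
            else:
                raise IntegrationUnderflowError(
                    f"stock {name!r} driven to {new:.6g} (level {level:.6g}, "
                    f"dt={dt}); reduce dt or check flow equations"
                )
        new_state[name] = new
    return new_state


def _net_rates(
    state: Mapping[str, float], flows: Sequence[FlowValue]
) -> dict[str, float]:
    net: dict[str, float] = {}
    for f in flows:
        if f.rate < 0:
            raise ValueError(f"flow {f.name!r} has negative rate {f.rate}")
        if f.source != EXTERNAL:
            if f.source not in state:
                raise KeyError(f"flow {f.name!r} drains unknown stock {f.source!r}")
            net[f.source] = net.get(f.source, 0.0) - f.rate
        if f.sink != EXTERNAL:
            if f.sink not in state:
                raise KeyError(f"flow {f.name!r} fills unknown stock {f.sink!r}")
            net[f.sink] = net.get(f.sink, 0.0) + f.rate
    return net


@dataclass
class Trajectory:
    """Time-indexed record of a simulation run.

    ``stocks``, ``aux`` and ``flows`` map names to arrays aligned with
    ``times``; ``flow_graph`` maps each flow name to its (source, sink).
    """

    times: np.ndarray
    stocks: dict[str, np.ndarray]
    aux: dict[str, np.ndarray]
    flows: dict[str, np.ndarray]
    flow_graph: dict[str, tuple[str, str]] = field(default_factory=dict)

    def index_of(self, t: float) -> int:
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > 1e-6:
            raise KeyError(f"time {t} is not on the trajectory grid")
        return i

    def at(self, name: str, t: float) -> float:
        """Value of a stock or auxiliary at grid time ``t``."""
        i = self.index_of(t)
        if name in self.stocks:
            return float(self.stocks[name][i])
        if name in self.aux:
            return float(self.aux[name][i])
        if name in self.flows:
            return float(self.flows[name][i])
        raise KeyError(name)

    def state_at(self, t: float) -> dict[str, float]:
        i = self.index_of(t)
        return {k: float(v[i]) for k, v in self.stocks.items()}

    def to_frame(self) -> pd.DataFrame:
        """Tidy long table: time, variable, kind, value."""
        frames = []
        for kind, table in (
            ("stock", self.stocks),
            ("aux", self.aux),
            ("flow", self.flows),
        ):
            for name, values in table.items():
                frames.append(
                    pd.DataFrame(
                        {
                            "time": self.times,
                            "variable": name,
                            "kind": kind,
                            "value": values,
                        }
                    )
                )
        return pd.concat(frames, ignore_index=True)


def _derivative(
    spec: ModelSpec, t: float, state: Mapping[str, float]
) -> dict[str, float]:
    aux = spec.auxiliaries(t, state)
    flows = spec.flows(t, state, aux)
    return _net_rates(state, flows)


def run_simulation(
    spec: ModelSpec, grid: TimeGrid, method: str = "euler"
) -> Trajectory:
    """Integrate a model over ``grid``, recording every variable at every point.

    ``method`` is ``"euler"`` (default) or ``"rk4"`` (classical
    Runge-Kutta, used as a higher-order reference).  Flows and
    auxiliaries recorded at each time are the beginning-of-step values.
    """
    if method not in ("euler", "rk4"):
        raise ValueError(f"unknown integration method {method!r}")
    times = grid.times()
    state = dict(spec.initial)
    for name, level in state.items():
        if level < 0:
            raise ValueError(f"initial stock {name!r} is negative ({level})")

    stock_rec: dict[str, list[float]] = {k: [] for k in state}
    aux_rec: dict[str, list[float]] = {}
    flow_rec: dict[str, list[float]] = {}
    flow_graph: dict[str, tuple[str, str]] = {}

    for i, t in enumerate(times):
        aux = spec.auxiliaries(t, state)
        flows = list(spec.flows(t, state, aux))
        for k in state:
            stock_rec[k].append(state[k])
        if i == 0:
            aux_rec = {k: [] for k in aux}
            flow_rec = {f.name: [] for f in flows}
            flow_graph = {f.name: (f.source, f.sink) for f in flows}
        for k, v in aux.items():
            aux_rec[k].append(v)
        for f in flows:
            flow_rec[f.name].append(f.rate)
        if i == len(times) - 1:
            break
        if method == "euler":
            state = euler_step(state, flows, grid.dt)
        else:
            state = _rk4_step(spec, t, state, flows, grid.dt)

    return Trajectory(
        times=times,
        stocks={k: np.asarray(v) for k, v in stock_rec.items()},
        aux={k: np.asarray(v) for k, v in aux_rec.items()},
        flows={k: np.asarray(v) for k, v in flow_rec.items()},
        flow_graph=flow_graph,
    )


def _rk4_step(
    spec: ModelSpec,
    t: float,
    state: Mapping[str, float],
    flows_at_t: Sequence[FlowValue],
    dt: float,
) -> dict[str, float]:
    k1 = _net_rates(state, flows_at_t)

    def shifted(k: Mapping[str, float], h: float) -> dict[str, float]:
        return {n: max(0.0, state[n] + h * k.get(n, 0.0)) for n in state}

    k2 = _derivative(spec, t + dt / 2, shifted(k1, dt / 2))
    k3 = _derivative(spec, t + dt / 2, shifted(k2, dt / 2))
    k4 = _derivative(spec, t + dt, shifted(k3, dt))
    new_state = {}
    for n, level in state.items():
        incr = (
            k1.get(n, 0.0) + 2 * k2.get(n, 0.0) + 2 * k3.get(n, 0.0) + k4.get(n, 0.0)
        ) / 6.0
        new = level + dt * incr
        if new < 0.0:
            if new > -1e-9 * max(1.0, abs(level)):
                new = 0.0
            else:
                raise IntegrationUnderflowError(
                    f"stock {n!r} driven to {new:.6g} in RK4 step at t={t}"
                )
        new_state[n] = new
    return new_state
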
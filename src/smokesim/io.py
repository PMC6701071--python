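"""Plain-text I/O: CSV conventions for series and results, YAML configs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
import yaml

from . import __version__
from .engine import Trajectory
from .model import BehaviorParams, EnvInputs
from .policies import PolicyOutcome, PolicyScenario, outcomes_frame

__all__ = [
    "read_env_csv",
    "read_historical_csv",
    "read_params_yaml",
    "read_scenarios_yaml",
    "write_env_csv",
    "write_historical_csv",
    "write_manifest",
    "write_outcomes_csv",
    "write_params_yaml",
    "write_trajectory_csv",
]

_WIDE_COLUMNS = {
    "price": "retail_price",
    "tax": "excise_tax",
    "income": "income_index",
    "entry_middle": "entry_rate",
    "parent_prev": "parental_prevalence",
    "funding": "funding_per_capita",
}


def read_env_csv(path: str | Path, **overrides) -> EnvInputs:
    """Read a wide exogenous-series CSV: year,price,tax,income,entry_middle,parent_prev[,funding].

    Missing funding defaults to the CDC-recommended $9.80/capita;
    per-cohort compliance (scalars) may be passed as keyword overrides.
    """
    df = pd.read_csv(path)
    if "year" not in df.columns:
        raise ValueError(f"{path}: expected a 'year' column")
    kwargs: dict = {}
    for col, field in _WIDE_COLUMNS.items():
        if col in df.columns:
            kwargs[field] = dict(zip(df["year"].astype(float), df[col].astype(float)))
    missing = {"retail_price", "excise_tax", "income_index", "entry_rate",
               "parental_prevalence"} - set(kwargs)
    if missing:
        raise ValueError(f"{path}: missing series {sorted(missing)}")
    kwargs.setdefault("funding_per_capita", 9.80)
    kwargs.update(overrides)
    return EnvInputs(**kwargs)


def write_env_csv(env: EnvInputs, path: str | Path, years: Iterable[float]) -> None:
    years = list(years)
    pd.DataFrame(
        {
            "year": [int(y) for y in years],
            "price": [env.retail_price(y) for y in years],
            "tax": [env.excise_tax(y) for y in years],
            "income": [env.income_index(y) for y in years],
            "entry_middle": [env.entry_rate(y) for y in years],
            "parent_prev": [env.parental_prevalence(y) for y in years],
            "funding": [env.funding_per_capita(y) for y in years],
        }
    ).to_csv(path, index=False)


def read_historical_csv(path: str | Path) -> pd.DataFrame:
    """Historical prevalence CSV: year,cohort,prevalence."""
    df = pd.read_csv(path)
    required = {"year", "cohort", "prevalence"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: expected columns {sorted(required)}")
    return df


def write_historical_csv(series: pd.DataFrame, path: str | Path) -> None:
    series.to_csv(path, index=False)


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    """Tidy trajectory CSV: time,variable,cohort,value."""
    df = traj.to_frame()

    def split_cohort(name: str) -> tuple[str, str]:
        for suffix in ("_middle", "_high"):
            if name.endswith(suffix):
                return name[: -len(suffix)], suffix[1:].upper()
        return name, "ALL"

    parts = df["variable"].map(split_cohort)
    df["variable"] = [p[0] for p in parts]
    df["cohort"] = [p[1] for p in parts]
    df[["time", "variable", "cohort", "value"]].to_csv(path, index=False)


def write_outcomes_csv(outcomes: Iterable[PolicyOutcome], path: str | Path) -> None:
    outcomes_frame(outcomes).to_csv(path, index=False)


def read_params_yaml(path: str | Path) -> BehaviorParams:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return BehaviorParams(**data)


def write_params_yaml(params: BehaviorParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params.to_dict(), fh, sort_keys=False)


def read_scenarios_yaml(path: str | Path) -> dict[str, PolicyScenario]:
    """Scenario YAML: a list of mappings with the PolicyScenario field names."""
    with open(path) as fh:
        entries = yaml.safe_load(fh) or []
    scenarios = {}
    for entry in entries:
        s = PolicyScenario(**entry)
        scenarios[s.name] = s
    return scenarios


def write_manifest(
    out_dir: str | Path, config: Mapping, seed: int | None = None
) -> Path:
    """Record enough (config hash, seed, version, time) to reproduce a run."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    blob = json.dumps(_jsonable(config), sort_keys=True).encode()
    manifest = {
        "smokesim_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "config_sha256": hashlib.sha256(blob).hexdigest(),
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S%z"),
    }
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, Mapping):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if isinstance(obj, (str, int, float, bool)) or obj is None:
        return obj
    return repr(obj)
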
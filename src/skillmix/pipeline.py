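"""End-to-end orchestration: inputs -> demand -> LP -> report.

A run takes a scenario, a year (or year range), population and risk
structures, a timing table and cadre capacities, and produces per-cadre
whole-time-equivalent requirements.  Inputs default to the bundled England
fixture with the synthetic stand-in timing table; every input can be
replaced by a CSV/YAML file in the documented schemas.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from .capacity import CadreCapacity, default_capacities
from .careplan import CARE_BANDS, TimingTable
from .optimiser import WorkforceResult, round_for_report, solve_lp
from .population import (
    AgeCategory,
    PopulationTable,
    RiskProfile,
    derive_residual_category,
    load_population_table,
    population_at,
    risk_rate_at,
)
from .scenarios import (
    DemandVector,
    ScenarioSpec,
    builtin_scenarios,
    demand_by_cadre,
    map_to_care_bands,
    validate_scenario,
)

__all__ = ["RunConfig", "run_single", "run_projection", "write_report", "load_config"]

log = logging.getLogger("skillmix")


@dataclass
class RunConfig:
    """Everything one run needs; ``None`` fields fall back to the fixture."""

    scenario: "str | ScenarioSpec" = "a"
    year: int = 2023
    from_year: int | None = None
    to_year: int | None = None
    step: int = 1
    population: "PopulationTable | str | None" = None
    risk: "RiskProfile | str | None" = None
    timings: "TimingTable | str | None" = None
    capacities: "Mapping[str, CadreCapacity] | str | None" = None
    risk_start: tuple[int, float] | None = None   # (year, percent)
    risk_end: tuple[int, float] | None = None
    attendance_rate: float = 1.0
    urgent_uplift: float = 0.0
    urgent_minutes: float = 0.0
    rounding: str = "nearest"
    charge_confirmatory: bool = False
    seed: int = 0


def _resolve_scenario(scenario: "str | ScenarioSpec") -> ScenarioSpec:
    if isinstance(scenario, ScenarioSpec):
        return scenario
    for s in builtin_scenarios():
        if s.name == scenario:
            return s
    path = Path(scenario)
    if path.exists():
        return scenario_from_yaml(path)
    raise ValueError(f"unknown scenario {scenario!r}")


def scenario_from_yaml(path: "str | Path") -> ScenarioSpec:
    """Load a user-defined scenario: component -> cadre(:share) rules."""
    from .scenarios import plan_eligibility

    doc = yaml.safe_load(Path(path).read_text())
    shares: dict = {}
    for comp, cells in plan_eligibility().items():
        rule = doc["rules"][comp]
        if isinstance(rule, str):
            cell_shares = {rule: 1.0}
        else:
            cell_shares = {str(c): float(s) for c, s in rule.items()}
        for band, risk in cells:
            shares[(comp, band, risk)] = dict(cell_shares)
    split = None
    if "population_split" in doc:
        ps = doc["population_split"]
        split = (str(ps["stratum"]), float(ps["fraction"]), str(ps["cadre"]))
    return ScenarioSpec(str(doc.get("name", path)), shares, population_split=split)


def _resolve_population(src) -> PopulationTable:
    from .synth import england_population

    if src is None:
        return england_population()
    if isinstance(src, PopulationTable):
        return src
    return derive_residual_category(load_population_table(pd.read_csv(src)))


def _resolve_risk(config: RunConfig) -> RiskProfile:
    from .synth import england_risk_profile

    src = config.risk
    if src is None:
        profile = england_risk_profile()
    elif isinstance(src, RiskProfile):
        profile = src
    else:
        df = pd.read_csv(src)
        profile = RiskProfile(
            high_risk_fraction={
                AgeCategory.parse(str(r["age_category"])): float(r["high_risk_fraction"])
                for _, r in df.iterrows()
            }
        )
    if config.risk_start and config.risk_end:
        (y0, r0), (y1, r1) = config.risk_start, config.risk_end
        profile = replace(profile, trajectory=(int(y0), float(r0), int(y1), float(r1)))
    return profile


def _resolve_timings(src) -> TimingTable:
    from .synth import standin_timing_table

    if src is None:
        return standin_timing_table()
    if isinstance(src, TimingTable):
        return src
    return TimingTable.from_frame(pd.read_csv(src))


def _resolve_capacities(src) -> dict[str, CadreCapacity]:
    if src is None:
        return default_capacities()
    if isinstance(src, Mapping):
        return dict(src)
    df = pd.read_csv(src)
    return {
        str(r["cadre"]): CadreCapacity(
            str(r["cadre"]), float(r["nhs_hours_per_week"]), float(r["leave_weeks"])
        )
        for _, r in df.iterrows()
    }


def run_single(config: RunConfig) -> tuple[WorkforceResult, DemandVector, dict]:
    """One year, one scenario: returns (workforce, demand, run metadata)."""
    try:
        scenario = _resolve_scenario(config.scenario)
        bad = validate_scenario(scenario)
        if bad:
            raise ValueError("; ".join(bad))
    except Exception as exc:
        raise RuntimeError(f"scenario stage failed: {exc}") from exc

    try:
        pop_table = _resolve_population(config.population)
        profile = _resolve_risk(config)
        bands = map_to_care_bands(population_at(pop_table, config.year))
        if profile.trajectory is not None:
            fractions = profile.fractions_at(config.year, bands)
            rate = risk_rate_at(profile, config.year)
        else:
            fractions = dict(profile.high_risk_fraction)
            rate = profile.overall_rate(bands)
    except Exception as exc:
        raise RuntimeError(f"population/risk stage failed: {exc}") from exc

    try:
        table = _resolve_timings(config.timings)
        demand = demand_by_cadre(
            scenario,
            bands,
            fractions,
            table,
            attendance_rate=config.attendance_rate,
            urgent_uplift=config.urgent_uplift,
            urgent_minutes=config.urgent_minutes,
            charge_confirmatory=config.charge_confirmatory,
        )
    except Exception as exc:
        raise RuntimeError(f"demand stage failed: {exc}") from exc

    try:
        caps = _resolve_capacities(config.capacities)
        result = round_for_report(solve_lp(demand, caps), config.rounding)
    except Exception as exc:
        raise RuntimeError(f"optimiser stage failed: {exc}") from exc

    meta = {
        "scenario": scenario.name,
        "year": config.year,
        "population_used": sum(bands.values()),
        "risk_rate_used": rate,
        "demand_minutes": {g: demand.minutes[g] for g in sorted(demand.minutes)},
        "status": result.status,
    }
    log.info("run %s/%s: demand=%s status=%s", scenario.name, config.year,
             meta["demand_minutes"], result.status)
    return result, demand, meta


def run_projection(config: RunConfig) -> pd.DataFrame:
    """One :func:`run_single` per year of the range, with interpolation.

    Returns one row per (year, scenario, cadre) plus the combined totals.
    """
    y0 = config.from_year if config.from_year is not None else config.year
    y1 = config.to_year if config.to_year is not None else config.year
    rows = []
    for year in range(y0, y1 + 1, config.step):
        result, _, meta = run_single(replace(config, year=year))
        for cadre in sorted(result.wte_continuous):
            rows.append(
                {
                    "year": year,
                    "scenario": meta["scenario"],
                    "cadre": cadre,
                    "wte_continuous": result.wte_continuous[cadre],
                    "wte_reported": result.wte_reported[cadre],
                    "combined_total": result.combined_total,
                    "risk_rate_used": meta["risk_rate_used"],
                    "population_used": meta["population_used"],
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "year", "scenario", "cadre", "wte_continuous", "wte_reported",
            "combined_total", "risk_rate_used", "population_used",
        ],
    )


def write_report(results: pd.DataFrame, path: "str | Path", format: str = "csv") -> Path:
    """Write a projection table bit-stably (sorted rows, fixed precision)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = results.copy()
    if not df.empty:
        df = df.sort_values(["year", "scenario", "cadre"]).reset_index(drop=True)
        df["wte_continuous"] = df["wte_continuous"].map(lambda v: round(float(v), 2))
        df["risk_rate_used"] = df["risk_rate_used"].map(lambda v: round(float(v), 2))
    if format == "csv":
        df.to_csv(path, index=False, float_format="%.2f")
    elif format == "json":
        payload = df.to_dict(orient="records")
        path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")
    return path


def load_config(path: "str | Path") -> RunConfig:
    """RunConfig from a single YAML file mirroring the dataclass fields."""
    doc = yaml.safe_load(Path(path).read_text()) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    unknown = set(doc) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key in ("risk_start", "risk_end"):
        if key in doc and doc[key] is not None:
            doc[key] = tuple(doc[key])
    return RunConfig(**doc)
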
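"""Skill-mix delegation scenarios and per-cadre demand assembly.

A scenario assigns, for every (component, age band, risk) cell of the
preventive plan, a share of delivery to each cadre (dentist, DH/DTh, EDDN),
optionally carving out a fraction of one risk stratum whose whole plan goes
to a single cadre.  Demand in minutes is then

    population(band) x stratum fraction x attendance x share x minutes/year

summed over cells.  Scope-of-practice rules constrain which cadres may
receive shares of which components.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .careplan import (
    CADRES,
    CARE_BANDS,
    COMPONENT_SCOPE,
    RISK_LEVELS,
    BAND_10_17,
    BAND_5_9,
    CoverageError,
    TimingTable,
)
from .population import AgeCategory

__all__ = [
    "ScenarioSpec",
    "DemandVector",
    "scope_of_practice",
    "builtin_scenarios",
    "validate_scenario",
    "demand_by_cadre",
    "plan_eligibility",
    "map_to_care_bands",
]

Cell = tuple[str, AgeCategory, str]

_ALL = [(b, r) for b in CARE_BANDS for r in RISK_LEVELS]
_HIGH = [(b, "high") for b in CARE_BANDS]


def plan_eligibility() -> dict[str, list[tuple[AgeCategory, str]]]:
    """Which (band, risk) cells each plan component applies to.

    Universal elements (exam, varnish, oral-health and diet advice) reach
    every child; radiographs, sealants and restorative care are additional
    high-risk elements (radiographs and sealants from age 5); very brief
    advice on tobacco/vaping is for 10-17-year-olds regardless of risk.
    """
    return {
        "exam": list(_ALL),
        "radiographs": [(BAND_5_9, "high"), (BAND_10_17, "high")],
        "fluoride_varnish": list(_ALL),
        "fissure_sealants": [(BAND_5_9, "high"), (BAND_10_17, "high")],
        "oh_advice": list(_ALL),
        "diet_advice": list(_ALL),
        "vba": [(BAND_10_17, "high"), (BAND_10_17, "low")],
        "restorative": list(_HIGH),
    }


def scope_of_practice(cadre: str, component: str) -> bool:
    """Whether a registrant group may deliver a plan component."""
    if component not in COMPONENT_SCOPE:
        raise ValueError(f"unknown component {component!r}")
    if cadre not in CADRES:
        raise ValueError(f"unknown cadre {cadre!r}")
    return cadre in COMPONENT_SCOPE[component]


@dataclass
class ScenarioSpec:
    """A named delegation pattern.

    ``shares`` maps (component, band, risk) -> {cadre: fraction}; fractions
    over a cell must sum to 1.  ``population_split`` optionally routes a
    fraction of one risk stratum wholly to a single cadre's full plan
    before the shares apply, e.g. 10% of high-risk children to dentists.
    """

    name: str
    shares: dict[Cell, dict[str, float]]
    population_split: tuple[str, float, str] | None = None  # (stratum, fraction, cadre)

    def cadres_used(self) -> set[str]:
        used = {c for cell in self.shares.values() for c, s in cell.items() if s > 0}
        if self.population_split:
            used.add(self.population_split[2])
        return used


def _uniform(rules: Mapping[str, str]) -> dict[Cell, dict[str, float]]:
    """Expand component->cadre rules over the canonical eligibility grid."""
    shares: dict[Cell, dict[str, float]] = {}
    for comp, cells in plan_eligibility().items():
        cadre = rules[comp]
        for band, risk in cells:
            shares[(comp, band, risk)] = {cadre: 1.0}
    return shares


def builtin_scenarios() -> list[ScenarioSpec]:
    """The six delegation scenarios, in increasing order of skill-mix use.

    a) no skill mix, dentists deliver everything;
    b) no skill mix, DH/DThs deliver everything;
    c) moderate: DH/DThs examine and provide sealants, radiographs and
       restorative care, EDDNs everything else;
    d) intermediate: dentists examine, EDDNs apply varnish, DH/DThs the rest;
    e) combination: 10% of high-risk children receive their whole plan from
       dentists, the remainder delegated as in (c);
    f) maximum: dentists assess everyone, DH/DThs provide sealants,
       radiographs and restorations, EDDNs everything else in their scope.
    """
    c_rules = {
        "exam": "dh_dth",
        "radiographs": "dh_dth",
        "fissure_sealants": "dh_dth",
        "restorative": "dh_dth",
        "fluoride_varnish": "eddn",
        "oh_advice": "eddn",
        "diet_advice": "eddn",
        "vba": "eddn",
    }
    d_rules = {
        "exam": "dentist",
        "fluoride_varnish": "eddn",
        "radiographs": "dh_dth",
        "fissure_sealants": "dh_dth",
        "restorative": "dh_dth",
        "oh_advice": "dh_dth",
        "diet_advice": "dh_dth",
        "vba": "dh_dth",
    }
    f_rules = dict(c_rules, exam="dentist")
    return [
        ScenarioSpec("a", _uniform({c: "dentist" for c in plan_eligibility()})),
        ScenarioSpec("b", _uniform({c: "dh_dth" for c in plan_eligibility()})),
        ScenarioSpec("c", _uniform(c_rules)),
        ScenarioSpec("d", _uniform(d_rules)),
        ScenarioSpec("e", _uniform(c_rules), population_split=("high", 0.10, "dentist")),
        ScenarioSpec("f", _uniform(f_rules)),
    ]


def validate_scenario(spec: ScenarioSpec) -> list[str]:
    """Return human-readable violations; empty list means valid."""
    violations: list[str] = []
    for (comp, band, risk), cell in spec.shares.items():
        total = sum(cell.values())
        if abs(total - 1.0) > 1e-9:
            violations.append(
                f"{spec.name}: shares for ({comp}, {band.label}, {risk}) sum to {total}"
            )
        for cadre, share in cell.items():
            if share < 0 or share > 1:
                violations.append(
                    f"{spec.name}: share {share} for {cadre} outside [0,1]"
                )
            if share > 0 and not scope_of_practice(cadre, comp):
                violations.append(
                    f"{spec.name}: {cadre} out of scope for {comp}"
                )
    if spec.population_split is not None:
        stratum, frac, cadre = spec.population_split
        if stratum not in RISK_LEVELS:
            violations.append(f"{spec.name}: unknown split stratum {stratum!r}")
        if not 0 <= frac <= 1:
            violations.append(f"{spec.name}: split fraction {frac} outside [0,1]")
        if cadre not in CADRES:
            violations.append(f"{spec.name}: unknown split cadre {cadre!r}")
    return violations


@dataclass
class DemandVector:
    """Assigned annual demand in minutes per cadre, with full breakdown.

    ``applications`` counts children served per plan cell, which is
    scenario-invariant: delegation moves work between cadres but never
    changes who is treated.
    """

    minutes: dict[str, float] = field(default_factory=dict)
    breakdown: dict[tuple[str, str, AgeCategory, str], float] = field(default_factory=dict)
    applications: dict[Cell, float] = field(default_factory=dict)

    def total(self) -> float:
        return sum(self.minutes.values())


def map_to_care_bands(
    population: Mapping[AgeCategory, float],
    bands: tuple[AgeCategory, ...] = CARE_BANDS,
) -> dict[AgeCategory, float]:
    """Aggregate source age bands onto the care-plan bands.

    Source bands nested in a care band are summed; a straddling band is
    split pro-rata by single-year span (uniform-age assumption).
    """
    out = {b: 0.0 for b in bands}
    for src, n in population.items():
        for band in bands:
            lo = max(src.min_age, band.min_age)
            hi = min(src.max_age, band.max_age)
            if hi >= lo:
                out[band] += n * (hi - lo + 1) / src.span
    return out


def demand_by_cadre(
    spec: ScenarioSpec,
    population: Mapping[AgeCategory, float],
    risk_fractions: Mapping[AgeCategory, float],
    table: TimingTable,
    attendance_rate: float = 1.0,
    urgent_uplift: float = 0.0,
    urgent_minutes: float = 0.0,
    urgent_cadre: str = "dentist",
    charge_confirmatory: bool = False,
) -> DemandVector:
    """Annual minutes of assigned work per cadre under a scenario.

    ``population`` is keyed by the care bands (see :func:`map_to_care_bands`);
    ``risk_fractions`` gives each band's high-risk fraction.  ``attendance_rate``
    scales the attending population (1.0 models universal annual attendance);
    ``urgent_uplift`` adds ``uplift x total population x urgent_minutes`` of
    urgent care to ``urgent_cadre``.  ``charge_confirmatory`` adds the EDDN
    confirmatory examination wherever EDDNs deliver care in a cell whose
    examination is not routed to a dentist or DH/DTh.
    """
    bad = validate_scenario(spec)
    if bad:
        raise ValueError("invalid scenario: " + "; ".join(bad))
    if not 0 <= attendance_rate <= 1:
        raise ValueError("attendance_rate must be in [0, 1]")
    if urgent_uplift > 0 and urgent_minutes <= 0:
        raise ValueError("urgent_uplift requires a positive urgent visit duration")

    split_stratum, split_frac, split_cadre = (
        spec.population_split if spec.population_split else (None, 0.0, None)
    )

    dv = DemandVector(minutes={c: 0.0 for c in CADRES})

    def add(cadre: str, comp: str, band: AgeCategory, risk: str, mins: float) -> None:
        if mins == 0.0:
            return
        dv.minutes[cadre] += mins
        key = (cadre, comp, band, risk)
        dv.breakdown[key] = dv.breakdown.get(key, 0.0) + mins

    for (comp, band, risk), cell in spec.shares.items():
        frac_high = risk_fractions.get(band, 0.0)
        if not 0 <= frac_high <= 1:
            raise ValueError(f"risk fraction {frac_high} for {band.label} outside [0,1]")
        stratum_frac = frac_high if risk == "high" else 1.0 - frac_high
        children = population.get(band, 0.0) * stratum_frac * attendance_rate
        dv.applications[(comp, band, risk)] = (
            dv.applications.get((comp, band, risk), 0.0) + children
        )

        carved = children * split_frac if risk == split_stratum else 0.0
        remainder = children - carved
        if carved > 0:
            mins = table.get(comp, band, risk, split_cadre)
            if mins == 0.0 and (comp, band, risk, split_cadre) not in table.entries:
                raise CoverageError(
                    f"no timing for ({comp}, {band.label}, {risk}, {split_cadre})"
                )
            add(split_cadre, comp, band, risk, carved * mins)
        for cadre, share in cell.items():
            if share <= 0 or remainder <= 0:
                continue
            if (comp, band, risk, cadre) not in table.entries:
                raise CoverageError(
                    f"no timing for ({comp}, {band.label}, {risk}, {cadre})"
                )
            add(cadre, comp, band, risk, remainder * share * table.get(comp, band, risk, cadre))

    if charge_confirmatory:
        for band in CARE_BANDS:
            for risk in RISK_LEVELS:
                exam_cell = spec.shares.get(("exam", band, risk), {})
                examined = sum(
                    s for c, s in exam_cell.items() if c in ("dentist", "dh_dth")
                )
                eddn_active = any(
                    s > 0
                    for (comp, b, r), cell in spec.shares.items()
                    for c, s in cell.items()
                    if b == band and r == risk and c == "eddn"
                )
                if eddn_active and examined == 0:
                    frac_high = risk_fractions.get(band, 0.0)
                    stratum = frac_high if risk == "high" else 1.0 - frac_high
                    children = population.get(band, 0.0) * stratum * attendance_rate
                    add(
                        "eddn", "confirmatory_exam", band, risk,
                        children * table.get("confirmatory_exam", band, risk, "eddn"),
                    )

    if urgent_uplift > 0:
        total_pop = sum(population.values())
        dv.minutes[urgent_cadre] += urgent_uplift * total_pop * urgent_minutes

    return dv
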
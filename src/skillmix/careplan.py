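"""Evidence-based preventive care plan as annual minutes per child.

Each care component (examination, radiographs, fluoride varnish, fissure
sealants, oral-health and diet advice, very brief advice on tobacco/vaping,
restorative care, and the nurse confirmatory examination) is converted to
minutes per child per year for every (age band, caries-risk level, cadre)
cell, applying the plan's structural rules:

* fissure-sealant chair time is a once-per-tooth cost amortised evenly over
  the years of the age band (4 sealants for high-risk 5-9s, 12 for 10-17s);
* fluoride varnish is applied 3x/year to high-risk and 2x/year to low-risk
  children, with no varnish for 0-year-olds (no dentition) and low-risk
  varnish restricted to 3-4-year-olds within the 0-4 band;
* radiographs are never taken for 0-4s;
* extended-duties dental nurses (EDDNs) share DH/DTh timings except that
  their examination is a short confirmatory check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .population import AgeCategory

__all__ = [
    "CADRES",
    "RISK_LEVELS",
    "CARE_BANDS",
    "CareComponent",
    "TimingTable",
    "amortised_minutes_per_year",
    "varnish_schedule",
    "build_timing_table",
    "annual_care_minutes",
]

CADRES = ("dentist", "dh_dth", "eddn")
RISK_LEVELS = ("high", "low")

# care-plan age bands; the 10-14 and derived 15-17 population bands merge
# into 10-17 for demand purposes
BAND_0_4 = AgeCategory(0, 4)
BAND_5_9 = AgeCategory(5, 9)
BAND_10_17 = AgeCategory(10, 17)
CARE_BANDS = (BAND_0_4, BAND_5_9, BAND_10_17)

# which components each registrant group may deliver; EDDNs are limited to
# prevention delivered under prescription (no diagnosis, radiographs,
# sealants or restorations)
COMPONENT_SCOPE: dict[str, frozenset[str]] = {
    "exam": frozenset({"dentist", "dh_dth"}),
    "radiographs": frozenset({"dentist", "dh_dth"}),
    "fluoride_varnish": frozenset(CADRES),
    "fissure_sealants": frozenset({"dentist", "dh_dth"}),
    "oh_advice": frozenset(CADRES),
    "diet_advice": frozenset(CADRES),
    "vba": frozenset(CADRES),
    "restorative": frozenset({"dentist", "dh_dth"}),
    "confirmatory_exam": frozenset({"eddn"}),
}


class ScopeError(ValueError):
    """A component is assigned to a cadre outside its scope of practice."""


class CoverageError(KeyError):
    """A timing-table cell required by the computation is absent."""


def amortised_minutes_per_year(
    units_total: float, minutes_per_unit: float, span_years: float
) -> float:
    """Spread a once-per-child procedure cost evenly over an age band.

    A sealant is placed once per tooth per child, so the total chair time
    ``units_total * minutes_per_unit`` is divided across the band's years.
    """
    if span_years < 1:
        raise ValueError(f"span_years must be >= 1, got {span_years}")
    if units_total < 0 or minutes_per_unit < 0:
        raise ValueError("units and minutes must be nonnegative")
    return units_total * minutes_per_unit / span_years


def varnish_schedule(category: AgeCategory, risk: str) -> tuple[float, float]:
    """Fluoride-varnish (applications/year, eligible fraction of the band).

    High risk: 3/yr for ages 1-17 (0-year-olds have no dentition).
    Low risk: 2/yr, and within 0-4 only the 3-4-year-olds.  Single-year
    ages are assumed uniformly distributed within a band.
    """
    if risk not in RISK_LEVELS:
        raise ValueError(f"unknown risk level {risk!r}")
    freq = 3.0 if risk == "high" else 2.0
    eligible_min = 1 if risk == "high" else (3 if category.min_age < 5 else category.min_age)
    lo = max(category.min_age, eligible_min)
    if category.min_age >= 5:
        lo = category.min_age
    eligible_years = max(0, category.max_age - lo + 1)
    return freq, eligible_years / category.span


@dataclass
class CareComponent:
    """One element of the preventive plan.

    ``unit_minutes`` maps cadre -> minutes per application.  ``frequency``
    is applications/year (varnish frequency is resolved per cell by
    :func:`varnish_schedule` instead).  ``amortisation`` maps an age band
    to (units_total, span_years) for once-per-tooth procedures.
    """

    id: str
    eligibility: frozenset[tuple[AgeCategory, str]]
    unit_minutes: dict[str, float]
    frequency: float = 1.0
    amortisation: dict[AgeCategory, tuple[float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.frequency < 0:
            raise ValueError("frequency must be nonnegative")
        allowed = COMPONENT_SCOPE.get(self.id)
        for cadre, mins in self.unit_minutes.items():
            if mins < 0:
                raise ValueError(f"negative minutes for {self.id}/{cadre}")
            if allowed is not None and cadre not in allowed:
                raise ScopeError(f"{cadre} may not deliver {self.id}")
        for _, (units, span) in self.amortisation.items():
            if span < 1:
                raise ValueError("amortisation span must be >= 1 year")
            if units < 0:
                raise ValueError("amortised unit count must be nonnegative")


@dataclass
class TimingTable:
    """Minutes per child per year keyed by (component, band, risk, cadre)."""

    entries: dict[tuple[str, AgeCategory, str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for key, mins in self.entries.items():
            if mins < 0:
                raise ValueError(f"negative timing entry {key}")
            comp, _, _, cadre = key
            allowed = COMPONENT_SCOPE.get(comp)
            if allowed is not None and cadre not in allowed:
                raise ScopeError(f"{cadre} may not deliver {comp}")

    def get(self, component: str, band: AgeCategory, risk: str, cadre: str) -> float:
        return self.entries.get((component, band, risk, cadre), 0.0)

    def components(self) -> set[str]:
        return {k[0] for k in self.entries}

    def cells(self) -> set[tuple[AgeCategory, str]]:
        return {(k[1], k[2]) for k in self.entries}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "component": comp,
                "age_category": band.label,
                "risk": risk,
                "cadre": cadre,
                "minutes_per_year": mins,
            }
            for (comp, band, risk, cadre), mins in sorted(
                self.entries.items(), key=lambda kv: (kv[0][0], kv[0][1], kv[0][2], kv[0][3])
            )
        ]
        return pd.DataFrame(
            rows, columns=["component", "age_category", "risk", "cadre", "minutes_per_year"]
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimingTable":
        entries = {}
        for _, row in df.iterrows():
            key = (
                str(row["component"]),
                AgeCategory.parse(str(row["age_category"])),
                str(row["risk"]),
                str(row["cadre"]),
            )
            entries[key] = float(row["minutes_per_year"])
        return cls(entries)


def build_timing_table(components: Iterable[CareComponent]) -> TimingTable:
    """Resolve component definitions into per-year minutes for every cell.

    Per-year minutes are frequency x eligible-fraction x unit minutes plus
    any amortised once-per-tooth term for the band.  Varnish frequency and
    eligibility come from :func:`varnish_schedule`; radiograph entries are
    never produced for the 0-4 band.
    """
    entries: dict[tuple[str, AgeCategory, str, str], float] = {}
    for comp in components:
        for band, risk in comp.eligibility:
            if comp.id == "radiographs" and band.max_age <= 4:
                continue
            if comp.id == "fluoride_varnish":
                freq, frac = varnish_schedule(band, risk)
            else:
                freq, frac = comp.frequency, 1.0
            for cadre, unit in comp.unit_minutes.items():
                minutes = freq * frac * unit
                if band in comp.amortisation:
                    units, span = comp.amortisation[band]
                    minutes = amortised_minutes_per_year(units, unit, span)
                entries[(comp.id, band, risk, cadre)] = minutes
    return TimingTable(entries)


def annual_care_minutes(
    table: TimingTable, band: AgeCategory, risk: str, cadre: str,
    components: Iterable[str] | None = None,
) -> float:
    """Total plan minutes per child per year for one (band, risk, cadre).

    With ``components`` given, every named component must be present in the
    cell; missing ones raise :class:`CoverageError` listing the absences.
    """
    if components is not None:
        missing = [
            c for c in components if (c, band, risk, cadre) not in table.entries
        ]
        if missing:
            raise CoverageError(
                f"no timing for {sorted(missing)} at ({band.label}, {risk}, {cadre})"
            )
    return sum(
        mins
        for (comp, b, r, cd), mins in table.entries.items()
        if b == band and r == risk and cd == cadre
        and (components is None or comp in components)
    )
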
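"""Annual NHS clinical minutes available per whole-time-equivalent clinician.

Defaults reflect English NHS working patterns: dentists and extended-duties
dental nurses average 26.7 NHS hours/week; dental hygienists/therapists
work about 25 h/week of which 47.2% is NHS, collapsed to 11.8 NHS h/week.
All cadres take 4.4 weeks annual leave, and the model assumes every cadre's
NHS clinical time is dedicated wholly to children.
"""

from __future__ import annotations

from dataclasses import dataclass

from .careplan import CADRES

__all__ = ["CadreCapacity", "annual_available_minutes", "default_capacities"]


def annual_available_minutes(hours_per_week: float, leave_weeks: float) -> float:
    """NHS clinical minutes per WTE per year: hours x 60 x (52 - leave)."""
    if not 0 <= leave_weeks <= 52:
        raise ValueError(f"leave_weeks must be in [0, 52], got {leave_weeks}")
    if hours_per_week < 0:
        raise ValueError("hours_per_week must be nonnegative")
    return hours_per_week * 60.0 * (52.0 - leave_weeks)


@dataclass(frozen=True)
class CadreCapacity:
    cadre: str
    nhs_hours_per_week: float
    leave_weeks: float

    @property
    def annual_minutes(self) -> float:
        return annual_available_minutes(self.nhs_hours_per_week, self.leave_weeks)


def default_capacities(
    dh_dth_total_hours: float = 25.0, dh_dth_nhs_share: float = 0.472
) -> dict[str, CadreCapacity]:
    """Working-pattern defaults per cadre.

    The DH/DTh NHS share is exposed so changed commitment can be explored;
    with the defaults it reproduces the collapsed 11.8 h/week figure.
    """
    dh_hours = round(dh_dth_total_hours * dh_dth_nhs_share, 1)
    caps = {
        "dentist": CadreCapacity("dentist", 26.7, 4.4),
        "dh_dth": CadreCapacity("dh_dth", dh_hours, 4.4),
        "eddn": CadreCapacity("eddn", 26.7, 4.4),
    }
    assert set(caps) == set(CADRES)
    return caps
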
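"""Workforce linear programme.

Minimise total whole-time-equivalent (WTE) workforce x_g >= 0, one decision
variable per cadre g, subject to each cadre's annual capacity meeting its
assigned demand:  min sum_g x_g  s.t.  H_g x_g >= D_g.  Solved with the
HiGHS LP solver; every returned solution is re-checked for feasibility.
Because delegation shares fix D_g before solving, the programme separates
per cadre with closed-form optimum x_g = D_g / H_g — kept here as an
independent verification oracle for the solver path.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from scipy.optimize import linprog

from .capacity import CadreCapacity
from .scenarios import DemandVector

__all__ = ["WorkforceResult", "solve_lp", "closed_form_oracle", "round_for_report"]

FEASIBILITY_TOL = 1e-6  # absolute minutes


@dataclass
class WorkforceResult:
    wte_continuous: dict[str, float] = field(default_factory=dict)
    wte_reported: dict[str, int] = field(default_factory=dict)
    objective_value: float = 0.0
    status: str = "solved"  # or "infeasible"
    rounding: str | None = None

    @property
    def combined_total(self) -> int:
        return int(sum(self.wte_reported.values()))

    def continuous_total(self) -> float:
        return sum(self.wte_continuous.values())


def _capacities_minutes(capacities: Mapping[str, "CadreCapacity | float"]) -> dict[str, float]:
    return {
        g: (c.annual_minutes if isinstance(c, CadreCapacity) else float(c))
        for g, c in capacities.items()
    }


def _check_feasible(x: Mapping[str, float], demand: Mapping[str, float],
                    cap: Mapping[str, float]) -> None:
    for g, d in demand.items():
        if cap.get(g, 0.0) * x.get(g, 0.0) < d - FEASIBILITY_TOL:
            raise AssertionError(f"capacity constraint violated for {g}")


def solve_lp(
    demand: "DemandVector | Mapping[str, float]",
    capacities: Mapping[str, "CadreCapacity | float"],
) -> WorkforceResult:
    """Minimum-WTE workforce meeting the assigned demand, via the LP solver.

    A cadre with positive demand but zero capacity makes the programme
    infeasible; this is reported in ``status`` rather than raised.
    """
    dmap = demand.minutes if isinstance(demand, DemandVector) else dict(demand)
    cap = _capacities_minutes(capacities)
    cadres = sorted(dmap)

    for g in cadres:
        if dmap[g] < 0:
            raise ValueError(f"negative demand for {g}")
        if dmap[g] > 0 and cap.get(g, 0.0) <= 0:
            return WorkforceResult(status="infeasible")

    active = [g for g in cadres if dmap[g] > 0]
    x = {g: 0.0 for g in cadres}
    if active:
        c = np.ones(len(active))
        # H_g x_g >= D_g  ->  -H_g x_g <= -D_g
        a_ub = -np.diag([cap[g] for g in active])
        b_ub = -np.asarray([dmap[g] for g in active])
        res = linprog(c, A_ub=a_ub, b_ub=b_ub, bounds=(0, None), method="highs")
        if not res.success:
            return WorkforceResult(status="infeasible")
        x.update({g: float(v) for g, v in zip(active, res.x)})
    _check_feasible(x, dmap, cap)
    return WorkforceResult(
        wte_continuous=x,
        wte_reported={g: int(round(v)) for g, v in x.items()},
        objective_value=sum(x.values()),
        rounding="nearest",
    )


def closed_form_oracle(
    demand: "DemandVector | Mapping[str, float]",
    capacities: Mapping[str, "CadreCapacity | float"],
) -> WorkforceResult:
    """Per-cadre closed form x_g = D_g / H_g (the LP separates)."""
    dmap = demand.minutes if isinstance(demand, DemandVector) else dict(demand)
    cap = _capacities_minutes(capacities)
    x: dict[str, float] = {}
    for g in sorted(dmap):
        d = dmap[g]
        if d < 0:
            raise ValueError(f"negative demand for {g}")
        if d == 0:
            x[g] = 0.0
        elif cap.get(g, 0.0) <= 0:
            return WorkforceResult(status="infeasible")
        else:
            x[g] = d / cap[g]
    _check_feasible(x, dmap, cap)
    return WorkforceResult(
        wte_continuous=x,
        wte_reported={g: int(round(v)) for g, v in x.items()},
        objective_value=sum(x.values()),
        rounding="nearest",
    )


def round_for_report(result: WorkforceResult, mode: str = "nearest") -> WorkforceResult:
    """Integer WTE for reporting: half-up nearest, or ceil (requirements view)."""
    if result.status != "solved":
        return result
    if mode == "nearest":
        reported = {g: int(np.floor(v + 0.5)) for g, v in result.wte_continuous.items()}
    elif mode == "ceil":
        reported = {g: int(np.ceil(v - FEASIBILITY_TOL)) for g, v in result.wte_continuous.items()}
    else:
        raise ValueError(f"unknown rounding mode {mode!r}")
    return WorkforceResult(
        wte_continuous=dict(result.wte_continuous),
        wte_reported=reported,
        objective_value=result.objective_value,
        status=result.status,
        rounding=mode,
    )
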
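"""Sensitivity to attendance and urgent-care uplift, 2023.

Only about half of England's children attend an NHS dentist within a year,
so the universal-attendance figures are an upper bound: demand (and hence
WTE) scales linearly with the attendance rate.  An optional urgent-care
uplift adds 3% of the population x a 30-minute urgent visit to the dentist
workload.  Writes results/access_sensitivity.csv.
"""

from pathlib import Path

import pandas as pd

from skillmix.pipeline import RunConfig, run_projection, write_report

OUT = Path(__file__).resolve().parents[1] / "results"
URGENT_VISIT_MINUTES = 30.0


def main() -> None:
    frames = []
    for name in "abcdef":
        for attendance in (1.0, 0.527, 0.5):
            df = run_projection(
                RunConfig(scenario=name, from_year=2023, to_year=2023, attendance_rate=attendance)
            )
            df["attendance_rate"] = attendance
            df["urgent_uplift"] = 0.0
            frames.append(df)
        df = run_projection(
            RunConfig(
                scenario=name, from_year=2023, to_year=2023,
                urgent_uplift=0.03, urgent_minutes=URGENT_VISIT_MINUTES,
            )
        )
        df["attendance_rate"] = 1.0
        df["urgent_uplift"] = 0.03
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    path = write_report(table, OUT / "access_sensitivity.csv")
    print(f"Attendance and urgent-care sensitivity -> {path}")

    a = table[(table.scenario == "a") & (table.cadre == "dentist")]
    for _, row in a.iterrows():
        tag = f"attendance {row.attendance_rate:.1%}"
        if row.urgent_uplift:
            tag += f" + {row.urgent_uplift:.0%} urgent care ({URGENT_VISIT_MINUTES:.0f} min)"
        print(f"scenario (a) dentists, {tag}: {row.wte_reported:,}")
    print("\nHalving attendance halves the requirement: current access levels need roughly half the modelled workforce.")


if __name__ == "__main__":
    main()
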
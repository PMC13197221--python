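"""Child population and caries-risk structure.

Holds the age-banded child population of England (census anchor plus
ONS-style projection totals) and the high-caries-risk profile that together
drive preventive-care demand.  Population totals between anchor years are
linearly interpolated; age-band shares are frozen at the most recent anchor
that reports band-level counts.  The overall high-risk rate follows a linear
trajectory in calendar year between two stated endpoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "AgeCategory",
    "PopulationTable",
    "RiskProfile",
    "load_population_table",
    "derive_residual_category",
    "population_at",
    "average_risk_rate",
    "risk_rate_at",
]


class SchemaError(ValueError):
    """Malformed input table (overlapping bands, unparseable labels)."""


class ConsistencyError(ValueError):
    """Internally inconsistent counts (totals do not reconcile)."""


@dataclass(frozen=True, order=True)
class AgeCategory:
    """A contiguous band of single ages, e.g. ``5-9`` (inclusive ends)."""

    min_age: int
    max_age: int

    def __post_init__(self) -> None:
        if self.min_age < 0 or self.max_age < self.min_age:
            raise ValueError(f"invalid age band {self.min_age}-{self.max_age}")

    @property
    def label(self) -> str:
        return f"{self.min_age}-{self.max_age}"

    @property
    def span(self) -> int:
        """Number of single-year ages covered (inclusive)."""
        return self.max_age - self.min_age + 1

    @classmethod
    def parse(cls, label: str) -> "AgeCategory":
        try:
            lo, hi = label.replace("–", "-").split("-")
            return cls(int(lo), int(hi))
        except (ValueError, AttributeError) as exc:
            raise SchemaError(f"cannot parse age category {label!r}") from exc

    def overlaps(self, other: "AgeCategory") -> bool:
        return self.min_age <= other.max_age and other.min_age <= self.max_age


@dataclass
class PopulationTable:
    """Counts by age band at anchor years, plus total-only projection anchors.

    ``anchors`` maps calendar year -> {AgeCategory: persons}; ``totals``
    maps year -> persons for years where only a total is known (projection
    rows).  Years with band-level counts also appear in ``totals``.
    """

    anchors: dict[int, dict[AgeCategory, float]] = field(default_factory=dict)
    totals: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for year, bands in self.anchors.items():
            cats = sorted(bands)
            for a, b in zip(cats, cats[1:]):
                if a.overlaps(b):
                    raise SchemaError(f"overlapping bands {a.label}/{b.label} in {year}")
            for cat, n in bands.items():
                if n < 0:
                    raise ValueError(f"negative count for {cat.label} in {year}")
            self.totals.setdefault(year, sum(bands.values()))
        for year, tot in self.totals.items():
            if tot < 0:
                raise ValueError(f"negative total in {year}")
        if list(self.totals) != sorted(self.totals):
            self.totals = dict(sorted(self.totals.items()))

    @property
    def years(self) -> list[int]:
        return sorted(self.totals)

    def total(self, year: int) -> float:
        return self.totals[year]


def load_population_table(
    records: Iterable[Mapping] | pd.DataFrame, total_label: str = "0-17"
) -> PopulationTable:
    """Build a validated :class:`PopulationTable` from year/category/count rows.

    Rows labelled ``total_label`` (or spanning every other band in their
    year) are treated as totals; where a year has both band rows and a
    total row the band sum must match the total to within one person.
    """
    df = pd.DataFrame(records)
    required = {"year", "age_category", "count"}
    if not required.issubset(df.columns):
        raise SchemaError(f"population table needs columns {sorted(required)}")

    anchors: dict[int, dict[AgeCategory, float]] = {}
    totals: dict[int, float] = {}
    total_cats: dict[int, AgeCategory] = {}
    for _, row in df.iterrows():
        year = int(row["year"])
        count = float(row["count"])
        if count < 0:
            raise ValueError(f"negative count in year {year}")
        cat = AgeCategory.parse(str(row["age_category"]))
        if cat == AgeCategory.parse(total_label):
            totals[year] = count
            total_cats[year] = cat
            continue
        bands = anchors.setdefault(year, {})
        others = [c for c in bands if c != cat]
        if any(cat.overlaps(c) for c in others):
            # a band covering every other band in the year is a total row
            if all(cat.min_age <= c.min_age and c.max_age <= cat.max_age for c in others):
                totals[year] = count
                total_cats[year] = cat
                continue
            raise SchemaError(f"overlapping category {cat.label} in {year}")
        bands[cat] = count

    for year, tot in totals.items():
        bands = anchors.get(year) or {}
        if not bands:
            continue
        # bands that tile the whole total range leave no residual slot, so
        # their sum must reconcile with the stated total
        total_cat = total_cats.get(year)
        if total_cat is None:
            continue
        ages = {a for c in bands for a in range(c.min_age, c.max_age + 1)}
        tiles = ages == set(range(total_cat.min_age, total_cat.max_age + 1))
        band_sum = sum(bands.values())
        if tiles and abs(band_sum - tot) > 1.0:
            raise ConsistencyError(
                f"{year}: band sum {band_sum:,.0f} != stated total {tot:,.0f}"
            )

    table = PopulationTable(anchors={y: b for y, b in anchors.items() if b})
    table.totals.update(totals)
    table.totals = dict(sorted(table.totals.items()))
    return table


def derive_residual_category(table: PopulationTable, total_label: str = "0-17") -> PopulationTable:
    """Add the age band that the source table omits but whose total implies.

    The England source lists 0-4, 5-9 and 10-14 yet totals 0-17; the 15-17
    band is recovered by subtraction so the bands conserve the printed total.
    """
    total_cat = AgeCategory.parse(total_label)
    new_anchors: dict[int, dict[AgeCategory, float]] = {}
    for year, bands in table.anchors.items():
        bands = dict(bands)
        stated = table.totals.get(year)
        max_listed = max((c.max_age for c in bands), default=total_cat.min_age - 1)
        if stated is not None and max_listed < total_cat.max_age:
            listed = sum(bands.values())
            residual = stated - listed
            if residual < 0:
                raise ConsistencyError(
                    f"{year}: listed bands ({listed:,.0f}) exceed total ({stated:,.0f})"
                )
            bands[AgeCategory(max_listed + 1, total_cat.max_age)] = residual
        new_anchors[year] = bands
    out = PopulationTable(anchors=new_anchors)
    out.totals.update(table.totals)
    out.totals = dict(sorted(out.totals.items()))
    return out


def population_at(table: PopulationTable, year: int) -> dict[AgeCategory, float]:
    """Band-level population at ``year``.

    Exact at anchors; totals are linearly interpolated between adjacent
    anchors and split into bands using the shares of the most recent anchor
    that has band-level counts.  No extrapolation outside the anchor span.
    """
    years = table.years
    if not years:
        raise ValueError("empty population table")
    if year < years[0] or year > years[-1]:
        raise ValueError(f"year {year} outside anchor span {years[0]}-{years[-1]}")

    if year in table.totals:
        total = table.totals[year]
    else:
        lo = max(y for y in years if y < year)
        hi = min(y for y in years if y > year)
        w = (year - lo) / (hi - lo)
        total = (1 - w) * table.totals[lo] + w * table.totals[hi]

    share_years = [y for y in table.anchors if y <= year]
    if not share_years:
        share_years = sorted(table.anchors)[:1]
    if not share_years:
        raise ValueError("no anchor with band-level counts")
    ref = table.anchors[max(share_years)]
    ref_total = sum(ref.values())
    if ref_total == 0:
        return {cat: 0.0 for cat in ref}
    return {cat: total * n / ref_total for cat, n in ref.items()}


def average_risk_rate(
    fractions: Mapping[AgeCategory, float], weights: Mapping[AgeCategory, float]
) -> float:
    """Population-weighted mean high-risk fraction, as a percentage."""
    w_sum = 0.0
    acc = 0.0
    for cat, f in fractions.items():
        if not 0.0 <= f <= 1.0:
            raise ValueError(f"risk fraction {f} for {cat.label} outside [0,1]")
        w = weights.get(cat, 0.0)
        if w < 0:
            raise ValueError("negative weight")
        acc += w * f
        w_sum += w
    if w_sum == 0:
        raise ValueError("all-zero weights")
    return 100.0 * acc / w_sum


@dataclass
class RiskProfile:
    """Per-band high-risk fractions and a linear overall-rate trajectory.

    ``trajectory`` is (start_year, start_rate%, end_year, end_rate%).  Under
    a changed overall rate all band fractions scale proportionally — the
    sources report how risk varies by age at one time point only.
    """

    high_risk_fraction: dict[AgeCategory, float]
    trajectory: tuple[int, float, int, float] | None = None

    def __post_init__(self) -> None:
        for cat, f in self.high_risk_fraction.items():
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"fraction {f} for {cat.label} outside [0,1]")
        if self.trajectory is not None:
            y0, r0, y1, r1 = self.trajectory
            if y0 >= y1:
                raise ValueError("trajectory start_year must precede end_year")
            if not (0 <= r0 <= 100 and 0 <= r1 <= 100):
                raise ValueError("trajectory rates must be percentages in [0,100]")

    def overall_rate(self, weights: Mapping[AgeCategory, float]) -> float:
        return average_risk_rate(self.high_risk_fraction, weights)

    def fractions_at(
        self, year: int, weights: Mapping[AgeCategory, float]
    ) -> dict[AgeCategory, float]:
        """Band fractions rescaled so their weighted mean tracks the trajectory."""
        if self.trajectory is None:
            return dict(self.high_risk_fraction)
        target = risk_rate_at(self, year)
        base = self.overall_rate(weights)
        if base == 0:
            return dict(self.high_risk_fraction)
        scale = target / base
        return {c: min(1.0, f * scale) for c, f in self.high_risk_fraction.items()}


def risk_rate_at(profile: RiskProfile, year: float) -> float:
    """Overall high-risk rate (%) at ``year`` on the linear trajectory."""
    if profile.trajectory is None:
        raise ValueError("profile has no trajectory")
    y0, r0, y1, r1 = profile.trajectory
    if year < y0 or year > y1:
        raise ValueError(f"year {year} outside trajectory span {y0}-{y1}")
    w = (year - y0) / (y1 - y0)
    return (1 - w) * r0 + w * r1
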
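"""Delegation scenarios, scope of practice and demand assembly."""

import pytest
from hypothesis import given, settings, strategies as st

from skillmix.careplan import BAND_0_4, BAND_10_17, BAND_5_9, CARE_BANDS, CoverageError, TimingTable
from skillmix.population import AgeCategory
from skillmix.scenarios import (
    ScenarioSpec,
    builtin_scenarios,
    demand_by_cadre,
    map_to_care_bands,
    scope_of_practice,
    validate_scenario,
)


class TestScope:
    def test_eddn_limits(self):
        assert not scope_of_practice("eddn", "restorative")
        assert not scope_of_practice("eddn", "fissure_sealants")
        assert not scope_of_practice("eddn", "radiographs")
        assert not scope_of_practice("eddn", "exam")
        assert scope_of_practice("eddn", "fluoride_varnish")
        assert scope_of_practice("eddn", "confirmatory_exam")

    def test_dentist_full_scope(self):
        for comp in ("exam", "radiographs", "fluoride_varnish", "fissure_sealants",
                     "oh_advice", "diet_advice", "vba", "restorative"):
            assert scope_of_practice("dentist", comp)

    def test_unknown_component(self):
        with pytest.raises(ValueError):
            scope_of_practice("dentist", "orthodontics")


class TestBuiltins:
    def test_six_scenarios_all_valid(self):
        specs = builtin_scenarios()
        assert [s.name for s in specs] == list("abcdef")
        for spec in specs:
            assert validate_scenario(spec) == []

    def test_share_conservation(self):
        for spec in builtin_scenarios():
            for cell in spec.shares.values():
                assert sum(cell.values()) == pytest.approx(1.0, abs=1e-9)

    def test_scenario_a_all_dentist(self):
        a = next(s for s in builtin_scenarios() if s.name == "a")
        for cell in a.shares.values():
            assert cell == {"dentist": 1.0}

    def test_scenario_e_split(self):
        e = next(s for s in builtin_scenarios() if s.name == "e")
        assert e.population_split == ("high", 0.10, "dentist")

    def test_violations_reported_not_raised(self):
        bad_scope = ScenarioSpec("x", {("restorative", BAND_5_9, "high"): {"eddn": 1.0}})
        assert len(validate_scenario(bad_scope)) == 1
        bad_sum = ScenarioSpec("y", {("exam", BAND_5_9, "high"): {"dentist": 0.9}})
        assert len(validate_scenario(bad_sum)) == 1


class TestBandMapping:
    def test_source_bands_aggregate(self):
        pop = {
            AgeCategory(0, 4): 100.0,
            AgeCategory(5, 9): 200.0,
            AgeCategory(10, 14): 300.0,
            AgeCategory(15, 17): 150.0,
        }
        bands = map_to_care_bands(pop)
        assert bands[BAND_0_4] == 100.0
        assert bands[BAND_5_9] == 200.0
        assert bands[BAND_10_17] == 450.0

    def test_straddling_band_split_pro_rata(self):
        bands = map_to_care_bands({AgeCategory(0, 17): 1800.0})
        assert bands[BAND_0_4] == pytest.approx(500.0)
        assert bands[BAND_5_9] == pytest.approx(500.0)
        assert bands[BAND_10_17] == pytest.approx(800.0)


def _toy_demand(attendance=1.0, pop=1000.0, frac=0.4, hi=50.0, lo=20.0):
    table = TimingTable(
        {
            ("exam", band, risk, "dentist"): (hi if risk == "high" else lo)
            for band in CARE_BANDS
            for risk in ("high", "low")
        }
    )
    spec = ScenarioSpec(
        "toy",
        {("exam", band, risk): {"dentist": 1.0} for band in CARE_BANDS for risk in ("high", "low")},
    )
    bands = map_to_care_bands({AgeCategory(0, 17): pop})
    return demand_by_cadre(
        spec, bands, {b: frac for b in CARE_BANDS}, table, attendance_rate=attendance
    )


class TestDemand:
    def test_toy_hand_arithmetic(self):
        # 1,000 children x (0.4 x 50 + 0.6 x 20) minutes
        assert _toy_demand().minutes["dentist"] == pytest.approx(32_000.0)

    def test_attendance_halves_demand(self):
        full = _toy_demand(attendance=1.0)
        half = _toy_demand(attendance=0.5)
        for cadre in full.minutes:
            assert half.minutes[cadre] == pytest.approx(0.5 * full.minutes[cadre])

    def test_scenario_a_routes_nothing_to_dcps(self, standin, fixture_inputs):
        from skillmix.population import population_at

        a = next(s for s in builtin_scenarios() if s.name == "a")
        bands = map_to_care_bands(population_at(fixture_inputs["population"], 2023))
        dv = demand_by_cadre(a, bands, {b: 0.3102 for b in CARE_BANDS}, standin)
        assert dv.minutes["dh_dth"] == 0.0
        assert dv.minutes["eddn"] == 0.0
        assert dv.minutes["dentist"] > 0.0

    @settings(deadline=None, derandomize=True)
    @given(scale=st.floats(0.01, 100), att=st.floats(0.01, 1.0))
    def test_homogeneity_in_population_and_attendance(self, scale, att):
        base = _toy_demand()
        scaled = _toy_demand(pop=1000.0 * scale, attendance=att)
        assert scaled.minutes["dentist"] == pytest.approx(
            base.minutes["dentist"] * scale * att, rel=1e-9
        )

    @settings(deadline=None, derandomize=True)
    @given(bump=st.floats(0.0, 50.0), frac=st.floats(0.0, 1.0))
    def test_monotone_in_timings_and_risk(self, bump, frac):
        base = _toy_demand(frac=0.4, hi=50.0)
        more_time = _toy_demand(frac=0.4, hi=50.0 + bump)
        assert more_time.minutes["dentist"] >= base.minutes["dentist"] - 1e-9
        # high plan exceeds low plan, so raising the high-risk fraction
        # never lowers demand
        riskier = _toy_demand(frac=min(1.0, 0.4 + frac * 0.6))
        assert riskier.minutes["dentist"] >= base.minutes["dentist"] - 1e-9

    def test_applications_scenario_invariant(self, standin, fixture_inputs):
        from skillmix.population import population_at

        bands = map_to_care_bands(population_at(fixture_inputs["population"], 2023))
        fracs = {b: 0.3102 for b in CARE_BANDS}
        apps = [
            demand_by_cadre(s, bands, fracs, standin).applications
            for s in builtin_scenarios()
        ]
        for other in apps[1:]:
            assert set(other) == set(apps[0])
            for cell, n in apps[0].items():
                assert other[cell] == pytest.approx(n, rel=1e-12)

    def test_population_split_carves_full_plan(self, standin, fixture_inputs):
        from skillmix.careplan import annual_care_minutes
        from skillmix.population import population_at

        c, e = (next(s for s in builtin_scenarios() if s.name == n) for n in "ce")
        bands = map_to_care_bands(population_at(fixture_inputs["population"], 2023))
        fracs = {b: 0.3102 for b in CARE_BANDS}
        dv_c = demand_by_cadre(c, bands, fracs, standin)
        dv_e = demand_by_cadre(e, bands, fracs, standin)
        expected_dentist = 0.10 * sum(
            bands[b] * fracs[b] * annual_care_minutes(standin, b, "high", "dentist")
            for b in CARE_BANDS
        )
        assert dv_e.minutes["dentist"] == pytest.approx(expected_dentist, rel=1e-9)
        # the remainder is exactly 90% of (c)'s high-risk work plus all low-risk work
        assert dv_e.minutes["dh_dth"] < dv_c.minutes["dh_dth"]

    def test_missing_cell_raises_coverage_error(self, toy_scenario, toy_risk):
        bands = {b: 100.0 for b in CARE_BANDS}
        with pytest.raises(CoverageError):
            demand_by_cadre(toy_scenario, bands, toy_risk.high_risk_fraction, TimingTable({}))

    def test_urgent_uplift_requires_duration(self):
        spec = ScenarioSpec(
            "toy", {("exam", BAND_5_9, "high"): {"dentist": 1.0}}
        )
        table = TimingTable({("exam", BAND_5_9, "high", "dentist"): 10.0})
        with pytest.raises(ValueError):
            demand_by_cadre(spec, {BAND_5_9: 100.0}, {BAND_5_9: 0.5}, table, urgent_uplift=0.03)
        dv = demand_by_cadre(
            spec, {BAND_5_9: 100.0}, {BAND_5_9: 0.5}, table,
            urgent_uplift=0.03, urgent_minutes=20.0,
        )
        # 100 x 0.5 x 10 assigned care + 0.03 x 100 x 20 urgent care
        assert dv.minutes["dentist"] == pytest.approx(500.0 + 60.0)
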
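import pytest

from skillmix.careplan import CARE_BANDS, TimingTable
from skillmix.population import AgeCategory, RiskProfile, PopulationTable
from skillmix.scenarios import ScenarioSpec
from skillmix.synth import england_fixture, standin_timing_table

ENGLAND_ROWS = [
    {"year": 2022, "age_category": "0-4", "count": 3_237_500},
    {"year": 2022, "age_category": "5-9", "count": 3_542_074},
    {"year": 2022, "age_category": "10-14", "count": 3_436_207},
    {"year": 2022, "age_category": "0-17", "count": 12_097_402},
    {"year": 2023, "age_category": "0-17", "count": 12_059_255},
    {"year": 2030, "age_category": "0-17", "count": 11_643_646},
    {"year": 2040, "age_category": "0-17", "count": 10_807_953},
    {"year": 2050, "age_category": "0-17", "count": 11_121_906},
]


@pytest.fixture(scope="session")
def fixture_inputs():
    pop, risk, partial, caps, missing = england_fixture()
    return {"population": pop, "risk": risk, "partial": partial, "caps": caps, "missing": missing}


@pytest.fixture(scope="session")
def standin() -> TimingTable:
    return standin_timing_table()


@pytest.fixture()
def toy_population() -> PopulationTable:
    return PopulationTable(anchors={2023: {AgeCategory(0, 17): 1000.0}})


@pytest.fixture()
def toy_risk() -> RiskProfile:
    return RiskProfile(high_risk_fraction={b: 0.3102 for b in CARE_BANDS})


@pytest.fixture()
def toy_timings() -> TimingTable:
    entries = {}
    for band in CARE_BANDS:
        entries[("exam", band, "high", "dentist")] = 50.0
        entries[("exam", band, "low", "dentist")] = 20.0
    return TimingTable(entries)


@pytest.fixture()
def toy_scenario() -> ScenarioSpec:
    shares = {
        ("exam", band, risk): {"dentist": 1.0}
        for band in CARE_BANDS
        for risk in ("high", "low")
    }
    return ScenarioSpec("toy", shares)
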
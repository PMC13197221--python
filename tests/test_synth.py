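"""Synthetic-input generators, the England fixture, parameter recovery."""

import numpy as np
import pytest

from skillmix.careplan import BAND_0_4, BAND_10_17, BAND_5_9, CARE_BANDS, annual_care_minutes
from skillmix.population import AgeCategory, risk_rate_at
from skillmix.scenarios import validate_scenario
from skillmix.synth import (
    SynthConfig,
    generate_population,
    generate_risk_profile,
    generate_timing_table,
    parameter_recovery_check,
    standin_timing_table,
)


class TestGeneratePopulation:
    def test_counts_sum_exactly_to_total(self):
        config = SynthConfig(
            total_population=12_097_402, category_shares=(0.26, 0.29, 0.28, 0.17)
        )
        pop = generate_population(config)
        bands = pop.anchors[config.anchor_year]
        assert sum(bands.values()) == 12_097_402
        assert all(float(n).is_integer() for n in bands.values())

    def test_deterministic_per_seed(self):
        a = generate_population(SynthConfig(seed=7))
        b = generate_population(SynthConfig(seed=7))
        assert a.anchors == b.anchors

    def test_zero_total(self):
        pop = generate_population(SynthConfig(total_population=0))
        assert sum(pop.anchors[2023].values()) == 0

    def test_bad_shares_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(category_shares=(0.5, 0.2, 0.2, 0.2))


class TestGenerateRisk:
    def test_sd_zero_collapses_to_mean(self):
        profile = generate_risk_profile(SynthConfig(risk_sd=0.0, risk_mean=0.25))
        assert all(f == pytest.approx(0.25) for f in profile.high_risk_fraction.values())

    def test_clipping(self):
        profile = generate_risk_profile(SynthConfig(risk_mean=0.02, risk_sd=0.5, seed=11))
        assert all(0.0 <= f <= 1.0 for f in profile.high_risk_fraction.values())

    def test_monte_carlo_mean(self):
        # 1,000 seeds at Normal(0.31, 0.05): the mean overall rate
        # concentrates near the configured mean
        rates = []
        weights = {b: 1.0 for b in CARE_BANDS}
        for seed in range(1000):
            p = generate_risk_profile(SynthConfig(seed=seed, risk_mean=0.31, risk_sd=0.05))
            rates.append(p.overall_rate(weights) / 100.0)
        assert abs(np.mean(rates) - 0.31) < 0.005

    def test_seeds_differ(self):
        a = generate_risk_profile(SynthConfig(seed=1))
        b = generate_risk_profile(SynthConfig(seed=2))
        assert a.high_risk_fraction != b.high_risk_fraction


class TestGenerateTimings:
    def test_deterministic_and_seed_sensitive(self):
        assert generate_timing_table(SynthConfig(seed=5)).entries == generate_timing_table(
            SynthConfig(seed=5)
        ).entries
        assert generate_timing_table(SynthConfig(seed=5)).entries != generate_timing_table(
            SynthConfig(seed=6)
        ).entries

    @pytest.mark.parametrize("seed", range(0, 100, 7))
    def test_structural_rules_hold(self, seed):
        table = generate_timing_table(SynthConfig(seed=seed))
        assert all(m >= 0 for m in table.entries.values())
        for band in CARE_BANDS:
            for cadre in ("dentist", "dh_dth", "eddn"):
                assert annual_care_minutes(table, band, "high", cadre) >= annual_care_minutes(
                    table, band, "low", cadre
                )
        # amortisation: the 10-17 sealant rate is (12/8)/(4/5) of the 5-9 rate
        r59 = table.get("fissure_sealants", BAND_5_9, "high", "dentist")
        r1017 = table.get("fissure_sealants", BAND_10_17, "high", "dentist")
        assert r1017 == pytest.approx(r59 * (12 / 8) / (4 / 5))
        assert not any(
            comp == "radiographs" and band == BAND_0_4 for comp, band, _, _ in table.entries
        )

    def test_inverted_bounds_rejected(self):
        with pytest.raises(ValueError):
            SynthConfig(timing_bounds=(5.0, 1.0))


class TestEnglandFixture:
    def test_constants(self, fixture_inputs):
        pop = fixture_inputs["population"]
        assert pop.total(2022) == 12_097_402
        assert pop.anchors[2022][AgeCategory(15, 17)] == 1_881_621
        risk = fixture_inputs["risk"]
        assert risk_rate_at(risk, 2023) == pytest.approx(31.02)
        assert risk_rate_at(risk, 2050) == pytest.approx(16.56)
        caps = fixture_inputs["caps"]
        assert caps["dentist"].annual_minutes == pytest.approx(76_255.2)
        assert caps["dh_dth"].annual_minutes == pytest.approx(33_700.8)

    def test_partial_table_has_stated_entries_and_lists_gaps(self, fixture_inputs):
        partial = fixture_inputs["partial"]
        assert partial.get("fissure_sealants", BAND_5_9, "high", "dentist") == pytest.approx(7.44)
        assert partial.get("fissure_sealants", BAND_10_17, "high", "dentist") == pytest.approx(13.95)
        missing = fixture_inputs["missing"]
        assert missing, "unstated timing cells must be flagged, not silently filled"
        assert any(cell[0] == "exam" for cell in missing)

    def test_standin_fills_every_gap(self, fixture_inputs, standin):
        for cell in fixture_inputs["missing"]:
            assert cell in standin.entries


class TestParameterRecovery:
    def test_planted_vector_recovered(self):
        report = parameter_recovery_check(0, {"dentist": 10.0, "dh_dth": 20.0, "eddn": 30.0})
        assert report["ok"], report
        assert report["max_rel_err"] < 1e-6

    def test_zero_entry_recovered_as_zero(self):
        report = parameter_recovery_check(1, {"dentist": 0.0, "dh_dth": 20.0, "eddn": 30.0})
        assert report["ok"], report
        assert report["cadres"]["dentist"]["recovered"] == 0.0

    @pytest.mark.parametrize("seed", range(50))
    def test_recovery_across_seeds(self, seed):
        assert parameter_recovery_check(seed)["ok"]

    def test_generated_inputs_pass_validators(self):
        # generators produce inputs the downstream validators accept
        from skillmix.scenarios import builtin_scenarios

        for spec in builtin_scenarios():
            assert validate_scenario(spec) == []
        config = SynthConfig(seed=3)
        generate_population(config)
        generate_risk_profile(config)
        generate_timing_table(config)
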
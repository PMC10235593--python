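"""Parameter defaults, validation, and scenario-file round trips."""

import copy

import pytest

import cadecea as cc
from cadecea.params import (
    CI,
    CostItem,
    LesionClass as L,
    PopulationLabel,
    ScenarioValidationError,
    StateUtilityGroup as U,
    default_scenario,
    load_scenario,
    scenario_to_dict,
    validate,
    write_scenario,
)


class TestDefaults:
    """Every published input appears verbatim in the packaged base case."""

    @pytest.mark.parametrize("key,expected", [
        ("HEALTHY", 0.4043), (L.ADENOMA_SMALL, 0.3400), (L.ADENOMA_MEDIUM, 0.1064),
        (L.ADENOMA_LARGE, 0.1043), (L.CRC_I, 0.0237), (L.CRC_II, 0.0090),
        (L.CRC_III, 0.0123), (L.CRC_IV, 0.0),
    ])
    def test_fit_positive_distribution(self, base_config, key, expected):
        assert base_config.initial[key] == pytest.approx(expected)

    def test_distributions_sum_to_one(self):
        for pop in PopulationLabel:
            cfg = default_scenario(pop)
            assert cfg.initial.total() == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize("lesion,mean,lo,hi", [
        (L.ADENOMA_SMALL, 0.31, 0.25, 0.38),
        (L.ADENOMA_MEDIUM, 0.19, 0.12, 0.28),
        (L.ADENOMA_LARGE, 0.09, 0.04, 0.16),
    ])
    def test_adenoma_miss_rates(self, base_config, lesion, mean, lo, hi):
        assert base_config.detection.amr_conventional[lesion] == (mean, lo, hi)

    @pytest.mark.parametrize("lesion,mean,lo,hi", [
        (L.ADENOMA_SMALL, 1.64, 1.24, 2.18),
        (L.ADENOMA_MEDIUM, 1.64, 1.24, 2.18),
        (L.ADENOMA_LARGE, 1.07, 0.66, 1.74),
        (L.CRC_I, 3.36, 0.93, 12.11),
    ])
    def test_incidence_rate_ratios(self, base_config, lesion, mean, lo, hi):
        assert base_config.detection.irr[lesion] == (mean, lo, hi)

    @pytest.mark.parametrize("lesion,miss", [
        (L.ADENOMA_SMALL, 0.1726), (L.ADENOMA_MEDIUM, 0.0828), (L.ADENOMA_LARGE, 0.0760),
    ])
    def test_ai_aided_miss_rates(self, base_config, lesion, miss):
        assert base_config.detection.cade_miss_direct[lesion] == pytest.approx(miss)

    @pytest.mark.parametrize("key,mean,lo,hi", [
        ("small_to_medium", 0.035, 0.017, 0.069),
        ("medium_to_large", 0.022, 0.011, 0.043),
        ("large_to_crc_i", 0.370, 0.268, 0.472),
        ("crc_i_to_ii", 0.238, 0.206, 0.271),
        ("crc_ii_to_iii", 0.485, 0.321, 0.650),
        ("crc_iii_to_iv", 0.302, 0.151, 0.604),
    ])
    def test_progression_probabilities(self, base_config, key, mean, lo, hi):
        assert base_config.natural_history.progression[key] == (mean, lo, hi)

    def test_onset_knots(self, base_config):
        knots = base_config.natural_history.onset_by_age
        assert [(a, ci.mean) for a, ci in knots] == [
            (50, 0.008), (55, 0.010), (60, 0.012), (65, 0.013), (70, 0.015)]

    @pytest.mark.parametrize("stage,rate", [
        (L.CRC_I, 0.058), (L.CRC_II, 0.058), (L.CRC_III, 0.188), (L.CRC_IV, 0.188),
    ])
    def test_recurrence_rates(self, base_config, stage, rate):
        assert base_config.natural_history.recurrence_rate[stage] == rate

    @pytest.mark.parametrize("key,value", [
        (("I_II", "<65", False), 0.030), (("I_II", "65-75", False), 0.050),
        (("I_II", "75+", False), 0.105), (("III_IV", "<65", False), 0.050),
        (("III_IV", "65-75", False), 0.085), (("III_IV", "75+", False), 0.165),
        (("I_II", "<65", True), 0.560), (("I_II", "75+", True), 0.870),
        (("III_IV", "<65", True), 0.680), (("III_IV", "65-75", True), 0.670),
        (("III_IV", "75+", True), 0.935),
    ])
    def test_crc_mortality_table(self, base_config, key, value):
        assert base_config.natural_history.crc_mortality[key] == value

    @pytest.mark.parametrize("group,mean,lo,hi", [
        (U.ADENOMA, 0.91, 0.87, 0.93), (U.CRC_I_II, 0.67, 0.62, 0.72),
        (U.CRC_III, 0.59, 0.54, 0.69), (U.CRC_IV, 0.25, 0.20, 0.31),
    ])
    def test_utilities(self, base_config, group, mean, lo, hi):
        assert base_config.utilities.utility[group] == (mean, lo, hi)

    @pytest.mark.parametrize("item,base,plus15", [
        (CostItem.FIT, 31.11, 35.77),
        (CostItem.COLONOSCOPY, 688.00, 791.20),
        (CostItem.POLYPECTOMY, 413.00, 474.95),
        (CostItem.CRC_SURGERY, 12_082.00, 13_894.30),
        (CostItem.ADJUVANT_CHEMO_III, 9_637.00, 11_082.00),
        (CostItem.SYSTEMIC_CHEMO_IV, 11_442.00, 13_158.30),
        (CostItem.FOLLOWUP_STAGE_I, 306.00, 351.90),
        (CostItem.FOLLOWUP_STAGE_I_II, 1_427.85, 1_642.14),
    ])
    def test_costs(self, base_config, item, base, plus15):
        assert base_config.economics.cost[item] == (base, plus15)

    def test_economic_scalars(self, base_config):
        eco = base_config.economics
        assert eco.discount_rate == 0.035
        assert eco.wtp == 50_000.0
        assert eco.device_monthly_fee == 2250.0
        assert eco.annual_colonoscopy_volume == 1000.0
        assert eco.contract_years == 3.0

    def test_cohort_scalars(self, base_config):
        assert base_config.start_age == 50
        assert base_config.max_age == 100
        assert base_config.male_fraction == 0.545
        sv = base_config.surveillance
        assert (sv.negative_fit_interval, sv.low_risk_interval,
                sv.high_risk_interval) == (10, 5, 3)

    def test_default_passes_validation(self, base_config):
        assert validate(base_config) == []


class TestValidation:
    def test_distribution_sum_violation(self, base_config):
        cfg = copy.deepcopy(base_config)
        cfg.initial.probabilities["HEALTHY"] -= 0.02
        v = validate(cfg)
        assert len(v) == 1 and "initial" in v[0].field

    def test_negative_cost_violation(self, base_config):
        cfg = copy.deepcopy(base_config)
        cfg.economics.cost[CostItem.FIT] = (-5.0, 35.77)
        v = validate(cfg)
        assert len(v) == 1 and "FIT" in v[0].field

    def test_out_of_range_probability_names_field(self, base_config):
        cfg = copy.deepcopy(base_config)
        cfg.fit_sensitivity = 1.3
        v = validate(cfg)
        assert any(x.field == "fit_sensitivity" and x.value == 1.3 for x in v)


class TestScenarioIO:
    def test_empty_file_falls_back_to_defaults(self, tmp_path, base_config):
        p = tmp_path / "empty.yaml"
        p.write_text("")
        assert load_scenario(p) == base_config

    def test_partial_override(self, tmp_path, base_config):
        p = tmp_path / "nodisc.yaml"
        p.write_text("economics:\n  discount_rate: 0.0\n")
        cfg = load_scenario(p)
        assert cfg.economics.discount_rate == 0.0
        assert cfg.initial == base_config.initial

    def test_invalid_probability_raises_naming_field(self, tmp_path):
        p = tmp_path / "bad.yaml"
        p.write_text("fit_sensitivity: 1.3\n")
        with pytest.raises(ScenarioValidationError, match="fit_sensitivity"):
            load_scenario(p)

    def test_parse_failure(self, tmp_path):
        p = tmp_path / "broken.yaml"
        p.write_text("{::not yaml::")
        with pytest.raises(ValueError, match="parse"):
            load_scenario(p)

    def test_round_trip(self, tmp_path, base_config):
        cfg = copy.deepcopy(base_config)
        cfg.economics.wtp = 30_000.0
        cfg.fit_sensitivity = 0.8
        p = tmp_path / "scenario.yaml"
        write_scenario(cfg, p)
        back = load_scenario(p)
        assert back == cfg
        assert scenario_to_dict(back) == scenario_to_dict(cfg)

    def test_screening_population_alternative(self):
        cfg = default_scenario(PopulationLabel.SCREENING)
        assert cfg.initial.population_label == PopulationLabel.SCREENING
        assert cfg.initial["HEALTHY"] > 0.97
        assert cfg.initial.total() == pytest.approx(1.0, abs=1e-12)

    def test_life_table_csv_round_trip(self, tmp_path, base_config):
        p = tmp_path / "life.csv"
        base_config.life_table.to_csv(p)
        back = cc.LifeTable.from_csv(p)
        assert back.qx == base_config.life_table.qx
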
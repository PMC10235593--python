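"""Transition structure: onset, mortality, surveillance, one-cycle operator."""

import copy

import numpy as np
import pytest

import cadecea as cc
from cadecea.natural_history import (
    TransitionModel,
    age_band,
    build_transition_operator,
    colonoscopy_event,
    crc_mortality,
    onset_probability,
    progression_step,
    surveillance_interval,
)
from cadecea.params import CI, LesionClass as L, LifeTable
from cadecea.states import SPACE, CoreState, NextTest


def _zero_dynamics_config():
    """No onset, progression, presentation, recurrence or mortality."""
    cfg = cc.default_scenario()
    nh = cfg.natural_history
    nh.onset_by_age = [(50, CI(0.0))]
    nh.progression = {k: CI(0.0) for k in nh.progression}
    nh.presentation_rate = {k: 0.0 for k in nh.presentation_rate}
    nh.recurrence_rate = {k: 0.0 for k in nh.recurrence_rate}
    nh.crc_mortality = {k: 0.0 for k in nh.crc_mortality}
    cfg.life_table = LifeTable(qx={a: 0.0 for a in range(50, 111)})
    return cfg


class TestOnset:
    @pytest.mark.parametrize("age,expected", [
        (50, 0.008),    # first tabulated knot
        (52.5, 0.009),  # linear midpoint of 0.008 and 0.010
        (80, 0.015),    # constant extrapolation beyond the last knot
        (45, 0.008),    # constant extrapolation below the first knot
        (65, 0.013),
    ])
    def test_interpolation(self, base_config, age, expected):
        assert onset_probability(age, base_config.natural_history) == pytest.approx(expected)


class TestCrcMortality:
    def test_table_lookups(self, base_config):
        nh = base_config.natural_history
        assert crc_mortality(L.CRC_III, 60, False, nh) == 0.05
        assert crc_mortality(L.CRC_I, 80, True, nh) == 0.87
        assert crc_mortality(L.CRC_II, 50, False, nh) == 0.03

    def test_age_bands_are_half_open(self):
        assert age_band(64.9) == "<65"
        assert age_band(65) == "65-75"
        assert age_band(74.9) == "65-75"
        assert age_band(75) == "75+"

    def test_age_outside_range_errors(self, base_config):
        with pytest.raises(ValueError):
            crc_mortality(L.CRC_I, -3, False, base_config.natural_history)

    def test_non_crc_stage_rejected(self, base_config):
        with pytest.raises(ValueError):
            crc_mortality(L.ADENOMA_SMALL, 60, False, base_config.natural_history)


class TestSurveillanceInterval:
    def test_negative_colonoscopy_goes_to_fit(self):
        assert surveillance_interval(set()) == (10, NextTest.FIT)

    def test_low_risk_findings(self):
        assert surveillance_interval({L.ADENOMA_SMALL}) == (5, NextTest.COLONOSCOPY)
        assert surveillance_interval({L.ADENOMA_MEDIUM}) == (5, NextTest.COLONOSCOPY)

    def test_high_risk_findings(self):
        assert surveillance_interval({L.ADENOMA_LARGE}) == (3, NextTest.COLONOSCOPY)
        assert surveillance_interval({L.ADENOMA_SMALL}, n_polyps=3) == (3, NextTest.COLONOSCOPY)
        assert surveillance_interval({L.ADENOMA_SMALL}, high_grade_dysplasia=True) \
            == (3, NextTest.COLONOSCOPY)


class TestColonoscopyEvent:
    def _mass_at(self, core, clock=0, test=NextTest.COLONOSCOPY):
        v = np.zeros(SPACE.n)
        v[SPACE.ix(core, clock, test)] = 1.0
        return v

    def test_perfect_detection_resects_to_healthy_with_clock(self, base_config):
        cfg = copy.deepcopy(base_config)
        for c in (L.ADENOMA_SMALL, L.ADENOMA_MEDIUM, L.ADENOMA_LARGE):
            cfg.detection.amr_conventional[c] = CI(0.0)
        arm = cc.conventional_detection(cfg.detection)
        v = self._mass_at(CoreState.UNDETECTED_SMALL)
        out, _ = colonoscopy_event(v, arm, cfg)
        assert out[SPACE.ix(CoreState.HEALTHY, 5, NextTest.COLONOSCOPY)] == pytest.approx(1.0)

    def test_null_detection_changes_nothing_but_costs(self, base_config):
        cfg = copy.deepcopy(base_config)
        for c in (L.ADENOMA_SMALL, L.ADENOMA_MEDIUM, L.ADENOMA_LARGE):
            cfg.detection.amr_conventional[c] = CI(1.0)
        arm = cc.conventional_detection(cfg.detection)
        v = self._mass_at(CoreState.UNDETECTED_SMALL)
        out, cost = colonoscopy_event(v, arm, cfg)
        # the missed polyp stays undetected, scheduled for surveillance
        assert out.sum() == pytest.approx(1.0)
        assert out[SPACE.ix(CoreState.UNDETECTED_SMALL, 5, NextTest.COLONOSCOPY)] \
            == pytest.approx(1.0)
        assert cost == pytest.approx(688.0)

    def test_large_adenoma_detected_missed_split(self, base_config, conv_arm):
        v = self._mass_at(CoreState.UNDETECTED_LARGE)
        out, _ = colonoscopy_event(v, conv_arm, base_config)
        detected = out[SPACE.ix(CoreState.HEALTHY, 3, NextTest.COLONOSCOPY)]
        missed = out[SPACE.ix(CoreState.UNDETECTED_LARGE, 5, NextTest.COLONOSCOPY)]
        assert detected == pytest.approx(0.91)
        assert missed == pytest.approx(0.09)

    def test_states_off_schedule_untouched(self, base_config, conv_arm):
        v = self._mass_at(CoreState.UNDETECTED_LARGE, clock=4)
        out, cost = colonoscopy_event(v, conv_arm, base_config)
        assert np.allclose(out, v)
        assert cost == 0.0


class TestProgressionStep:
    def test_healthy_fixed_point_without_onset_or_death(self):
        cfg = _zero_dynamics_config()
        v = np.zeros(SPACE.n)
        v[SPACE.ix(CoreState.HEALTHY, 5, NextTest.FIT)] = 1.0
        out = progression_step(v, 50, cfg)
        assert np.allclose(out, v)

    def test_large_adenoma_progresses_to_crc(self):
        cfg = _zero_dynamics_config()
        cfg.natural_history.progression["large_to_crc_i"] = CI(0.37)
        v = np.zeros(SPACE.n)
        v[SPACE.ix(CoreState.UNDETECTED_LARGE, 5, NextTest.COLONOSCOPY)] = 1.0
        out = progression_step(v, 50, cfg)
        assert out[SPACE.ix(CoreState.UNDETECTED_CRC_I, 5, NextTest.COLONOSCOPY)] \
            == pytest.approx(0.37)

    def test_treated_stage_iii_recurrence(self):
        cfg = _zero_dynamics_config()
        cfg.natural_history.recurrence_rate[L.CRC_III] = 0.188
        v = np.zeros(SPACE.n)
        v[SPACE.ix(CoreState.TREATED_CRC_III)] = 1.0
        out = progression_step(v, 50, cfg)
        assert out[SPACE.ix(CoreState.CRC_RECURRENCE_III_IV)] == pytest.approx(0.188)

    def test_undetected_crc_presents_clinically(self, base_config):
        cfg = copy.deepcopy(base_config)
        cfg.life_table = LifeTable(qx={a: 0.0 for a in range(50, 111)})
        cfg.natural_history.crc_mortality = {k: 0.0 for k in cfg.natural_history.crc_mortality}
        cfg.natural_history.progression = {k: CI(0.0) for k in cfg.natural_history.progression}
        v = np.zeros(SPACE.n)
        v[SPACE.ix(CoreState.UNDETECTED_CRC_I, 5, NextTest.FIT)] = 1.0
        out = progression_step(v, 50, cfg)
        assert out[SPACE.ix(CoreState.TREATED_CRC_I)] == pytest.approx(0.20)


class TestOperator:
    @pytest.mark.parametrize("age", [50, 64, 65, 74, 75, 90, 100])
    def test_rows_sum_to_one(self, base_config, conv_arm, age):
        T = build_transition_operator(age, conv_arm, base_config)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-12)
        assert T.min() >= 0.0

    def test_death_rows_absorbing(self, base_config, cade_arm):
        T = build_transition_operator(60, cade_arm, base_config)
        for ix in (SPACE.death_crc_ix, SPACE.death_other_ix):
            row = np.zeros(SPACE.n)
            row[ix] = 1.0
            assert np.array_equal(T[ix], row)

    def test_zero_dynamics_operator_is_deterministic_clockwork(self):
        # with every rate zero, the only dynamics left are clocks and
        # scheduled tests: every row must be a unit mass on one state
        cfg = _zero_dynamics_config()
        arm = cc.conventional_detection(cfg.detection)
        T = build_transition_operator(55, arm, cfg)
        # brute-force check over the enumerated space
        healthy_rows = [i for i, s in enumerate(SPACE.states)
                        if s.core == CoreState.HEALTHY]
        for i in healthy_rows:
            assert np.isclose(T[i].max(), 1.0) and np.isclose(T[i].sum(), 1.0)
        # clocked states simply count down
        i = SPACE.ix(CoreState.HEALTHY, 7, NextTest.FIT)
        j = SPACE.ix(CoreState.HEALTHY, 6, NextTest.FIT)
        assert T[i, j] == 1.0

    def test_raising_sensitivity_reduces_undetected_crc_burden(self, base_config):
        disc = np.ones(50)
        crc_ix = [i for i, s in enumerate(SPACE.states)
                  if s.core.value.startswith("UNDETECTED_CRC")]

        def burden(arm):
            r = cc.run_arm(base_config, arm)
            return float(r.trace.occupancy[:50, crc_ix].sum())

        base_arm = cc.conventional_detection(base_config.detection)
        ref = burden(base_arm)
        for c in (L.ADENOMA_SMALL, L.ADENOMA_MEDIUM, L.ADENOMA_LARGE, L.CRC_I):
            arm = cc.conventional_detection(base_config.detection)
            arm.miss_rate[c] = max(0.0, arm.miss_rate[c] - 0.05)
            assert burden(arm) <= ref + 1e-9


class TestReducedChainOracle:
    def test_three_state_chain_matches_closed_form(self):
        """Healthy / undetected-small / dead chain vs hand-written recursion."""
        cfg = _zero_dynamics_config()
        q, p = 0.02, 0.01
        cfg.life_table = LifeTable(qx={a: q for a in range(50, 111)})
        cfg.natural_history.onset_by_age = [(50, CI(p))]
        # lesions are never detected: colonoscopy always misses, FIT never triggers
        for c in (L.ADENOMA_SMALL, L.ADENOMA_MEDIUM, L.ADENOMA_LARGE):
            cfg.detection.amr_conventional[c] = CI(1.0)
        cfg.fit_sensitivity = 0.0
        cfg.initial.probabilities = {k: 0.0 for k in cfg.initial.probabilities}
        cfg.initial.probabilities["HEALTHY"] = 1.0
        arm = cc.conventional_detection(cfg.detection)
        model = TransitionModel(cfg, arm)

        v = np.zeros(SPACE.n)
        v[SPACE.ix(CoreState.HEALTHY, 0, NextTest.COLONOSCOPY)] = 1.0
        h, s, d = 1.0, 0.0, 0.0
        for t in range(30):
            v, _ = model.step(v, 50 + t)
            # death first, then onset among survivors
            h, s, d = (h * (1 - q) * (1 - p),
                       s * (1 - q) + h * (1 - q) * p,
                       d + (h + s) * q)
            agg = {"H": 0.0, "S": 0.0, "D": 0.0}
            for i, st in enumerate(SPACE.states):
                if st.core == CoreState.HEALTHY:
                    agg["H"] += v[i]
                elif st.core == CoreState.UNDETECTED_SMALL:
                    agg["S"] += v[i]
                elif st.core == CoreState.DEATH_OTHER:
                    agg["D"] += v[i]
            assert agg["H"] == pytest.approx(h, abs=1e-12)
            assert agg["S"] == pytest.approx(s, abs=1e-12)
            assert agg["D"] == pytest.approx(d, abs=1e-12)
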
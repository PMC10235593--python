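"""Age-dependent annual transition structure of the disease model.

One model cycle (1 year) is the composition of four stages, in a fixed,
documented order:

1. scheduled test events (states whose surveillance clock reads 0):
   colonoscopy with arm-specific per-class sensitivity, or follow-up FIT
   which triggers a colonoscopy with probability ``fit_sensitivity`` when
   a lesion is present;
2. death: background all-cause mortality (life-table ``qx``) for every
   alive state, then CRC mortality among survivors of stage 1 for
   undetected CRC (stage-group "no recurrence" rates), treated stage IV,
   and the recurrence states ("post recurrence" rates);
3. progression among survivors: adenoma onset and growth, CRC stage
   progression (stage III to IV routes through systemic chemotherapy),
   and post-surgical recurrence;
4. surveillance-clock decrement.

Death is applied before progression; any fixed order is defensible at
1-year cycles and this one is a documented constant of the model.
"""

from __future__ import annotations

import numpy as np

from .detection import Arm, ArmDetection
from .params import (
    CostItem,
    LesionClass,
    NaturalHistoryParams,
    ScenarioConfig,
    SurveillancePolicy,
)
from .states import (
    LESION_OF_CORE,
    SPACE,
    CoreState,
    NextTest,
)

__all__ = [
    "onset_probability",
    "crc_mortality",
    "age_band",
    "surveillance_interval",
    "colonoscopy_event",
    "progression_step",
    "build_transition_operator",
    "TransitionModel",
]


def onset_probability(age: float, params: NaturalHistoryParams) -> float:
    """Annual healthy-to-small-adenoma probability, interpolated on age.

    Linear between the tabulated knot ages, constant beyond them.
    """
    knots = [(a, ci.mean) for a, ci in params.onset_by_age]
    ages = np.array([a for a, _ in knots], dtype=float)
    vals = np.array([p for _, p in knots], dtype=float)
    return float(np.interp(age, ages, vals))


def age_band(age: float) -> str:
    """Half-open age bands used by the CRC mortality table."""
    if age < 0 or age > 130:
        raise ValueError(f"age {age} outside model range")
    if age < 65:
        return "<65"
    if age < 75:
        return "65-75"
    return "75+"


def _stage_group(stage: LesionClass) -> str:
    if stage in (LesionClass.CRC_I, LesionClass.CRC_II):
        return "I_II"
    if stage in (LesionClass.CRC_III, LesionClass.CRC_IV):
        return "III_IV"
    raise ValueError(f"{stage} is not a CRC stage")


def crc_mortality(stage: LesionClass, age: float, recurrence: bool,
                  params: NaturalHistoryParams) -> float:
    """Annual CRC death probability by stage group, age band and recurrence."""
    return params.crc_mortality[(_stage_group(stage), age_band(age), bool(recurrence))]


def surveillance_interval(findings, policy: SurveillancePolicy | None = None,
                          n_polyps: int = 1, high_grade_dysplasia: bool = False):
    """Guideline follow-up after one colonoscopy's findings.

    No lesion: FIT after ``negative_fit_interval`` years.  Small/medium
    adenomas with fewer than three polyps and no high-grade dysplasia:
    colonoscopy after ``low_risk_interval``.  Large adenoma, three or
    more polyps, or high-grade dysplasia (and any CRC finding):
    colonoscopy after ``high_risk_interval``.
    """
    policy = policy or SurveillancePolicy()
    findings = set(findings)
    if not findings and not high_grade_dysplasia:
        return policy.negative_fit_interval, NextTest.FIT
    high_risk = (
        high_grade_dysplasia
        or n_polyps >= 3
        or any(f >= LesionClass.ADENOMA_LARGE for f in findings)
    )
    if high_risk:
        return policy.high_risk_interval, NextTest.COLONOSCOPY
    return policy.low_risk_interval, NextTest.COLONOSCOPY


class TransitionModel:
    """Precomputed one-cycle dynamics for one arm of one scenario.

    Row convention throughout: occupancy is a row vector ``v`` and one
    cycle maps it to ``step(v, age)``; the full one-cycle operator
    ``operator(age)`` satisfies ``v_next = v @ T`` with rows summing to 1.
    """

    def __init__(self, config: ScenarioConfig, arm: ArmDetection):
        self.cfg = config
        self.arm = arm
        self.space = SPACE
        n = self.space.n
        self._build_test_stage()
        self._build_progression_stage()
        # clock decrement permutation (watch states with clock >= 1)
        dec = np.arange(n)
        for i, s in enumerate(self.space.states):
            if s.next_test is not None and s.clock >= 1:
                dec[i] = self.space.ix(s.core, s.clock - 1, s.next_test)
        self._dec = dec
        # per-band CRC mortality vectors
        self._m_crc = {band: self._mortality_vector(band) for band in ("<65", "65-75", "75+")}
        self._alive_mask = np.zeros(n, dtype=bool)
        self._alive_mask[self.space.alive_ix] = True
        self._c_state = self._state_cost_vector()

    # -- stage builders ----------------------------------------------------

    def _crc_treatment(self, lesion: LesionClass):
        """(treated-state index, one-off treatment cost) on CRC diagnosis."""
        eco = self.cfg.economics
        ix = self.space.ix
        if lesion == LesionClass.CRC_I:
            return ix(CoreState.TREATED_CRC_I), eco.base_cost(CostItem.CRC_SURGERY)
        if lesion == LesionClass.CRC_II:
            return ix(CoreState.TREATED_CRC_II), eco.base_cost(CostItem.CRC_SURGERY)
        if lesion == LesionClass.CRC_III:
            return ix(CoreState.TREATED_CRC_III), (eco.base_cost(CostItem.CRC_SURGERY)
                                                   + eco.base_cost(CostItem.ADJUVANT_CHEMO_III))
        if lesion == LesionClass.CRC_IV:
            return ix(CoreState.TREATED_CRC_IV), eco.base_cost(CostItem.SYSTEMIC_CHEMO_IV)
        raise ValueError(f"{lesion} is not a CRC stage")

    def _colonoscopy_outcome(self, core: CoreState):
        """(targets: {state index: prob}, expected cost) of one colonoscopy."""
        cfg = self.cfg
        eco = cfg.economics
        pol = cfg.surveillance
        cost = eco.base_cost(CostItem.COLONOSCOPY)
        if self.arm.arm == Arm.CADE:
            cost += eco.device_cost_per_procedure()
        out: dict[int, float] = {}
        ix = self.space.ix
        if core == CoreState.HEALTHY:
            out[ix(CoreState.HEALTHY, pol.negative_fit_interval, NextTest.FIT)] = 1.0
            return out, cost
        lesion = LESION_OF_CORE[core]
        sens = 1.0 - self.arm.miss_rate[lesion]
        if lesion in (LesionClass.ADENOMA_SMALL, LesionClass.ADENOMA_MEDIUM,
                      LesionClass.ADENOMA_LARGE):
            interval, test = surveillance_interval({lesion}, pol)
            out[ix(CoreState.HEALTHY, interval, test)] = sens
            cost += sens * eco.base_cost(CostItem.POLYPECTOMY)
        else:
            j, treat_cost = self._crc_treatment(lesion)
            out[j] = sens
            cost += sens * treat_cost
        if sens < 1.0:
            if lesion in (LesionClass.ADENOMA_SMALL, LesionClass.ADENOMA_MEDIUM,
                          LesionClass.ADENOMA_LARGE):
                # missed polyp: retrieved at the follow-up examination — in a
                # FIT-positive cohort a missed adenoma typically coexists with
                # detected lesions, so surveillance colonoscopy follows at the
                # low-risk interval rather than the 10-year FIT
                out[ix(core, pol.low_risk_interval, NextTest.COLONOSCOPY)] = 1.0 - sens
            else:
                # missed CRC: the examination reads negative (FIT in 10 years);
                # clinical presentation can intervene between tests
                out[ix(core, pol.negative_fit_interval, NextTest.FIT)] = 1.0 - sens
        return out, cost

    def _build_test_stage(self):
        n = self.space.n
        E = np.zeros((n, n))
        c = np.zeros(n)
        pol = self.cfg.surveillance
        fit_cost = self.cfg.economics.base_cost(CostItem.FIT)
        fs = self.cfg.fit_sensitivity
        for i, s in enumerate(self.space.states):
            if s.next_test is None or s.clock != 0:
                E[i, i] = 1.0
                continue
            if s.next_test == NextTest.COLONOSCOPY:
                out, cost = self._colonoscopy_outcome(s.core)
                for j, p in out.items():
                    E[i, j] += p
                c[i] = cost
            else:  # FIT
                c[i] = fit_cost
                reset = self.space.ix(s.core, pol.negative_fit_interval, NextTest.FIT)
                if s.core == CoreState.HEALTHY:
                    # a negative FIT returns the patient to routine
                    # programmatic FIT screening (biennial)
                    E[i, self.space.ix(s.core, pol.fit_screening_interval,
                                       NextTest.FIT)] += 1.0
                else:
                    out, cost = self._colonoscopy_outcome(s.core)
                    for j, p in out.items():
                        E[i, j] += fs * p
                    E[i, reset] += 1.0 - fs
                    c[i] += fs * cost
        self._E = E
        self._c_test = c

    def _build_progression_stage(self):
        """Progression matrix (onset excluded; it is age-dependent)."""
        n = self.space.n
        P = np.eye(n)
        c = np.zeros(n)
        nh = self.cfg.natural_history
        prog = {k: ci.mean for k, ci in nh.progression.items()}
        chemo_iv = self.cfg.economics.base_cost(CostItem.SYSTEMIC_CHEMO_IV)
        ix = self.space.ix
        step_of = {
            CoreState.UNDETECTED_SMALL: (CoreState.UNDETECTED_MEDIUM, prog["small_to_medium"]),
            CoreState.UNDETECTED_MEDIUM: (CoreState.UNDETECTED_LARGE, prog["medium_to_large"]),
            CoreState.UNDETECTED_LARGE: (CoreState.UNDETECTED_CRC_I, prog["large_to_crc_i"]),
            CoreState.UNDETECTED_CRC_I: (CoreState.UNDETECTED_CRC_II, prog["crc_i_to_ii"]),
            CoreState.UNDETECTED_CRC_II: (CoreState.UNDETECTED_CRC_III, prog["crc_ii_to_iii"]),
        }
        for i, s in enumerate(self.space.states):
            if s.next_test is not None and s.core in step_of:
                target_core, p = step_of[s.core]
                j = ix(target_core, s.clock, s.next_test)
                P[i, i] -= p
                P[i, j] += p
            elif s.next_test is not None and s.core == CoreState.UNDETECTED_CRC_III:
                # stage IV entry by progression: systemic chemotherapy once
                p = prog["crc_iii_to_iv"]
                j = ix(CoreState.TREATED_CRC_IV)
                P[i, i] -= p
                P[i, j] += p
                c[i] = p * chemo_iv
        rec = nh.recurrence_rate
        pairs = [
            (CoreState.TREATED_CRC_I, CoreState.CRC_RECURRENCE_I_II, rec[LesionClass.CRC_I]),
            (CoreState.TREATED_CRC_II, CoreState.CRC_RECURRENCE_I_II, rec[LesionClass.CRC_II]),
            (CoreState.TREATED_CRC_III, CoreState.CRC_RECURRENCE_III_IV, rec[LesionClass.CRC_III]),
            (CoreState.TREATED_CRC_IV, CoreState.CRC_RECURRENCE_III_IV, rec[LesionClass.CRC_IV]),
        ]
        for src, dst, p in pairs:
            i, j = ix(src), ix(dst)
            P[i, i] -= p
            P[i, j] += p
        # clinical presentation of undetected CRC between scheduled tests:
        # with probability p the cancer is diagnosed (diagnostic colonoscopy)
        # and treated, and takes no further transition this cycle; with
        # probability 1-p it remains undetected and progresses as above
        pres = nh.presentation_rate or {}
        colo = self.cfg.economics.base_cost(CostItem.COLONOSCOPY)
        if self.arm.arm == Arm.CADE:
            colo += self.cfg.economics.device_cost_per_procedure()
        for i, s in enumerate(self.space.states):
            if s.next_test is None or s.core not in LESION_OF_CORE:
                continue
            lesion = LESION_OF_CORE[s.core]
            p = pres.get(lesion, 0.0)
            if lesion not in (LesionClass.CRC_I, LesionClass.CRC_II,
                              LesionClass.CRC_III, LesionClass.CRC_IV) or p == 0.0:
                continue
            j, treat_cost = self._crc_treatment(lesion)
            P[i, :] *= 1.0 - p
            P[i, j] += p
            c[i] = (1.0 - p) * c[i] + p * (colo + treat_cost)
        self._P = P
        self._c_prog = c
        # onset bookkeeping: healthy -> small adenoma with the same clock
        h_ix, s_ix = [], []
        for i, s in enumerate(self.space.states):
            if s.core == CoreState.HEALTHY:
                h_ix.append(i)
                s_ix.append(self.space.ix(CoreState.UNDETECTED_SMALL, s.clock, s.next_test))
        self._onset_from = np.array(h_ix)
        self._onset_to = np.array(s_ix)

    def _mortality_vector(self, band: str) -> np.ndarray:
        """Per-state annual CRC death probability for one age band."""
        nh = self.cfg.natural_history
        m = np.zeros(self.space.n)
        groups = {
            CoreState.UNDETECTED_CRC_I: ("I_II", False),
            CoreState.UNDETECTED_CRC_II: ("I_II", False),
            CoreState.UNDETECTED_CRC_III: ("III_IV", False),
            CoreState.UNDETECTED_CRC_IV: ("III_IV", False),
            CoreState.TREATED_CRC_IV: ("III_IV", False),
            CoreState.CRC_RECURRENCE_I_II: ("I_II", True),
            CoreState.CRC_RECURRENCE_III_IV: ("III_IV", True),
        }
        for i, s in enumerate(self.space.states):
            key = groups.get(s.core)
            if key is not None:
                m[i] = nh.crc_mortality[(key[0], age_band_lookup(band), key[1])]
        return m

    def _state_cost_vector(self) -> np.ndarray:
        """Annual disease-management costs by state occupancy.

        Surgically treated patients accrue the post-surgical follow-up
        bundle each year they remain recurrence-free (stage I at the
        stage-I rate, stages II/III at the stage I-II rate).  Stage-IV
        disease and recurrence of advanced (III/IV) disease accrue
        systemic chemotherapy each year on top of the first course costed
        at entry; recurrence after early-stage (I/II) surgery is managed
        with the intensive follow-up bundle (salvage rather than
        continuous palliative therapy).
        """
        eco = self.cfg.economics
        per_core = {
            CoreState.TREATED_CRC_I: eco.base_cost(CostItem.FOLLOWUP_STAGE_I),
            CoreState.TREATED_CRC_II: eco.base_cost(CostItem.FOLLOWUP_STAGE_I_II),
            CoreState.TREATED_CRC_III: eco.base_cost(CostItem.FOLLOWUP_STAGE_I_II),
            CoreState.TREATED_CRC_IV: eco.base_cost(CostItem.SYSTEMIC_CHEMO_IV),
            CoreState.CRC_RECURRENCE_I_II: eco.base_cost(CostItem.FOLLOWUP_STAGE_I_II),
            CoreState.CRC_RECURRENCE_III_IV: eco.base_cost(CostItem.SYSTEMIC_CHEMO_IV),
        }
        c = np.zeros(self.space.n)
        for i, s in enumerate(self.space.states):
            c[i] = per_core.get(s.core, 0.0)
        return c

    # -- per-cycle application --------------------------------------------

    def _apply_death(self, v: np.ndarray, age: float) -> np.ndarray:
        qx = self.cfg.life_table.prob(age)
        m = self._m_crc[age_band(age)]
        alive = self._alive_mask
        out = v.copy()
        live = v * alive
        d_other = qx * live.sum()
        d_crc = (1.0 - qx) * float(live @ m)
        out[alive] = live[alive] * (1.0 - qx) * (1.0 - m[alive])
        out[self.space.death_other_ix] += d_other
        out[self.space.death_crc_ix] += d_crc
        return out

    def _apply_onset(self, v: np.ndarray, age: float) -> np.ndarray:
        f = onset_probability(age, self.cfg.natural_history)
        if f == 0.0:
            return v
        moved = f * v[self._onset_from]
        v = v.copy()
        np.subtract.at(v, self._onset_from, moved)
        np.add.at(v, self._onset_to, moved)
        return v

    def _apply_decrement(self, v: np.ndarray) -> np.ndarray:
        out = np.zeros_like(v)
        np.add.at(out, self._dec, v)
        return out

    def step(self, v: np.ndarray, age: float) -> tuple[np.ndarray, float]:
        """Advance occupancy one cycle; return (next occupancy, cycle cost)."""
        cost = float(v @ self._c_test) + float(v @ self._c_state)
        v1 = v @ self._E
        v2 = self._apply_death(v1, age)
        cost += float(v2 @ self._c_prog)
        v3 = v2 @ self._P
        v3 = self._apply_onset(v3, age)
        return self._apply_decrement(v3), cost

    def operator(self, age: float) -> np.ndarray:
        """Full one-cycle transition matrix at one age (for microsimulation)."""
        n = self.space.n
        qx = self.cfg.life_table.prob(age)
        m = self._m_crc[age_band(age)]
        D = np.zeros((n, n))
        for i in range(n):
            if not self._alive_mask[i]:
                D[i, i] = 1.0
                continue
            D[i, i] = (1.0 - qx) * (1.0 - m[i])
            D[i, self.space.death_other_ix] += qx
            D[i, self.space.death_crc_ix] += (1.0 - qx) * m[i]
        P = self._P.copy()
        f = onset_probability(age, self.cfg.natural_history)
        for i, j in zip(self._onset_from, self._onset_to):
            P[i, i] -= f
            P[i, j] += f
        Dec = np.zeros((n, n))
        Dec[np.arange(n), self._dec] = 1.0
        T = self._E @ D @ P @ Dec
        if np.any(T < -1e-12):
            raise ValueError("negative entry in transition operator")
        return np.clip(T, 0.0, None)

    def cycle_cost_vector(self, age: float) -> np.ndarray:
        """Expected within-cycle cost given the start-of-cycle state."""
        n = self.space.n
        qx = self.cfg.life_table.prob(age)
        m = self._m_crc[age_band(age)]
        surv = np.where(self._alive_mask, (1.0 - qx) * (1.0 - m), 1.0)
        # cost of progression applies to post-test, post-death occupancy
        return self._c_test + self._c_state + self._E @ (surv * self._c_prog)


def age_band_lookup(band: str) -> str:
    """Identity helper kept for readability of the band-keyed tables."""
    if band not in ("<65", "65-75", "75+"):
        raise ValueError(f"unknown age band {band!r}")
    return band


# ---------------------------------------------------------------------------
# Functional wrappers over the staged model
# ---------------------------------------------------------------------------

def colonoscopy_event(occupancy: np.ndarray, arm: ArmDetection,
                      config: ScenarioConfig) -> tuple[np.ndarray, float]:
    """Apply scheduled test events to an occupancy vector.

    Only states whose clock reads 0 are affected; the expected resource
    cost of the events is returned alongside the post-event occupancy.
    """
    model = TransitionModel(config, arm)
    cost = float(occupancy @ model._c_test)
    return occupancy @ model._E, cost


def progression_step(occupancy: np.ndarray, age: float,
                     config: ScenarioConfig) -> np.ndarray:
    """One year of mortality, onset, progression and recurrence (no tests)."""
    from .detection import conventional_detection

    model = TransitionModel(config, conventional_detection(config.detection))
    v = model._apply_death(np.asarray(occupancy, dtype=float), age)
    v = v @ model._P
    return model._apply_onset(v, age)


def build_transition_operator(age: float, arm: ArmDetection,
                              config: ScenarioConfig) -> np.ndarray:
    """One-cycle operator over the expanded state space; rows sum to 1."""
    return TransitionModel(config, arm).operator(age)
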
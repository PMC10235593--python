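"""Expanded Markov state space with surveillance tunnel states.

The clinical core states (healthy, undetected adenoma by size, undetected
CRC by stage) are crossed with a surveillance clock — an integer count of
years until the next scheduled test, plus which test it is (FIT or
colonoscopy) — turning the guideline follow-up schedule into ordinary
tunnel states of a finite Markov chain.  Treated CRC, recurrence and the
two death states carry no clock.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .params import LesionClass

__all__ = ["CoreState", "NextTest", "ModelState", "StateSpace"]


class CoreState(enum.Enum):
    HEALTHY = "HEALTHY"
    UNDETECTED_SMALL = "UNDETECTED_SMALL"
    UNDETECTED_MEDIUM = "UNDETECTED_MEDIUM"
    UNDETECTED_LARGE = "UNDETECTED_LARGE"
    UNDETECTED_CRC_I = "UNDETECTED_CRC_I"
    UNDETECTED_CRC_II = "UNDETECTED_CRC_II"
    UNDETECTED_CRC_III = "UNDETECTED_CRC_III"
    UNDETECTED_CRC_IV = "UNDETECTED_CRC_IV"
    TREATED_CRC_I = "TREATED_CRC_I"
    TREATED_CRC_II = "TREATED_CRC_II"
    TREATED_CRC_III = "TREATED_CRC_III"
    TREATED_CRC_IV = "TREATED_CRC_IV"
    CRC_RECURRENCE_I_II = "CRC_RECURRENCE_I_II"
    CRC_RECURRENCE_III_IV = "CRC_RECURRENCE_III_IV"
    DEATH_CRC = "DEATH_CRC"
    DEATH_OTHER = "DEATH_OTHER"


#: cores that carry a surveillance clock
WATCH_CORES = (
    CoreState.HEALTHY,
    CoreState.UNDETECTED_SMALL,
    CoreState.UNDETECTED_MEDIUM,
    CoreState.UNDETECTED_LARGE,
    CoreState.UNDETECTED_CRC_I,
    CoreState.UNDETECTED_CRC_II,
    CoreState.UNDETECTED_CRC_III,
    CoreState.UNDETECTED_CRC_IV,
)

TREATED_CORES = (
    CoreState.TREATED_CRC_I,
    CoreState.TREATED_CRC_II,
    CoreState.TREATED_CRC_III,
    CoreState.TREATED_CRC_IV,
)

DEATH_CORES = (CoreState.DEATH_CRC, CoreState.DEATH_OTHER)

LESION_OF_CORE = {
    CoreState.UNDETECTED_SMALL: LesionClass.ADENOMA_SMALL,
    CoreState.UNDETECTED_MEDIUM: LesionClass.ADENOMA_MEDIUM,
    CoreState.UNDETECTED_LARGE: LesionClass.ADENOMA_LARGE,
    CoreState.UNDETECTED_CRC_I: LesionClass.CRC_I,
    CoreState.UNDETECTED_CRC_II: LesionClass.CRC_II,
    CoreState.UNDETECTED_CRC_III: LesionClass.CRC_III,
    CoreState.UNDETECTED_CRC_IV: LesionClass.CRC_IV,
}

CORE_OF_LESION = {v: k for k, v in LESION_OF_CORE.items()}

TREATED_OF_STAGE = {
    LesionClass.CRC_I: CoreState.TREATED_CRC_I,
    LesionClass.CRC_II: CoreState.TREATED_CRC_II,
    LesionClass.CRC_III: CoreState.TREATED_CRC_III,
    LesionClass.CRC_IV: CoreState.TREATED_CRC_IV,
}


class NextTest(str, enum.Enum):
    FIT = "FIT"
    COLONOSCOPY = "COLONOSCOPY"


MAX_FIT_CLOCK = 10
MAX_COL_CLOCK = 10  # colonoscopy intervals used are <= 5 y but the space allows 10


@dataclass(frozen=True)
class ModelState:
    core: CoreState
    clock: int = 0                 # years until next scheduled test (watch cores only)
    next_test: NextTest | None = None

    def label(self) -> str:
        if self.next_test is None:
            return self.core.value
        return f"{self.core.value}|{self.next_test.value}{self.clock}"


class StateSpace:
    """Enumeration of the expanded state space with index lookups."""

    def __init__(self):
        states: list[ModelState] = []
        for core in WATCH_CORES:
            for test, max_clock in ((NextTest.FIT, MAX_FIT_CLOCK),
                                    (NextTest.COLONOSCOPY, MAX_COL_CLOCK)):
                for clock in range(max_clock + 1):
                    states.append(ModelState(core, clock, test))
        for core in TREATED_CORES:
            states.append(ModelState(core))
        states.append(ModelState(CoreState.CRC_RECURRENCE_I_II))
        states.append(ModelState(CoreState.CRC_RECURRENCE_III_IV))
        states.append(ModelState(CoreState.DEATH_CRC))
        states.append(ModelState(CoreState.DEATH_OTHER))
        self.states = tuple(states)
        self.index = {s: i for i, s in enumerate(states)}
        self.n = len(states)

        self.death_other_ix = self.index[ModelState(CoreState.DEATH_OTHER)]
        self.death_crc_ix = self.index[ModelState(CoreState.DEATH_CRC)]
        self.alive_ix = [i for i, s in enumerate(states) if s.core not in DEATH_CORES]

    def ix(self, core: CoreState, clock: int = 0, next_test: NextTest | None = None) -> int:
        return self.index[ModelState(core, clock, next_test)]

    def __len__(self) -> int:
        return self.n


#: module-level shared instance (the space is config-independent)
SPACE = StateSpace()
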
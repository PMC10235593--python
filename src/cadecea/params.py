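"""Parameter schema, packaged defaults, and scenario-file I/O.

The model is fully parameterised by a :class:`ScenarioConfig`: the initial
FIT-positive (or screening) health-state distribution, colonoscopy miss
rates and the CADe effect measures, adenoma/CRC natural-history transition
probabilities, CRC mortality and recurrence, utility weights, unit costs,
discounting and the willingness-to-pay threshold.  The packaged defaults
are code, not a data file, so the package runs with no I/O; a YAML scenario
file can override any subset of fields (see :func:`load_scenario`).
"""

from __future__ import annotations

import copy
import dataclasses
import enum
import logging
from dataclasses import dataclass, field
from typing import Iterator

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "LesionClass",
    "ADENOMA_CLASSES",
    "CRC_CLASSES",
    "CI",
    "PopulationLabel",
    "CadeMissMode",
    "CostItem",
    "StateUtilityGroup",
    "InitialDistribution",
    "DetectionParams",
    "NaturalHistoryParams",
    "UtilityParams",
    "EconomicParams",
    "LifeTable",
    "SurveillancePolicy",
    "ScenarioConfig",
    "Violation",
    "ScenarioValidationError",
    "default_scenario",
    "load_scenario",
    "write_scenario",
    "scenario_to_dict",
    "scenario_from_dict",
    "validate",
]


class LesionClass(enum.IntEnum):
    """Lesion classes, totally ordered from small adenoma to stage-IV CRC."""

    ADENOMA_SMALL = 0   # <5 mm
    ADENOMA_MEDIUM = 1  # 6-9 mm
    ADENOMA_LARGE = 2   # >=10 mm
    CRC_I = 3
    CRC_II = 4
    CRC_III = 5
    CRC_IV = 6


ADENOMA_CLASSES = (
    LesionClass.ADENOMA_SMALL,
    LesionClass.ADENOMA_MEDIUM,
    LesionClass.ADENOMA_LARGE,
)
CRC_CLASSES = (
    LesionClass.CRC_I,
    LesionClass.CRC_II,
    LesionClass.CRC_III,
    LesionClass.CRC_IV,
)


class CI(tuple):
    """A (mean, lo, hi) triple; lo/hi are 95% interval bounds."""

    def __new__(cls, mean: float, lo: float | None = None, hi: float | None = None):
        lo = mean if lo is None else lo
        hi = mean if hi is None else hi
        return super().__new__(cls, (float(mean), float(lo), float(hi)))

    @property
    def mean(self) -> float:
        return self[0]

    @property
    def lo(self) -> float:
        return self[1]

    @property
    def hi(self) -> float:
        return self[2]

    def is_degenerate(self) -> bool:
        return self.lo == self.mean == self.hi

    def __getnewargs__(self):  # keeps copy/pickle going through __new__
        return tuple(self)


class PopulationLabel(str, enum.Enum):
    FIT_POSITIVE = "FIT_POSITIVE"
    SCREENING = "SCREENING"


class CadeMissMode(str, enum.Enum):
    DIRECT_TABLE = "DIRECT_TABLE"
    IRR_DERIVED = "IRR_DERIVED"


class CostItem(str, enum.Enum):
    FIT = "FIT"
    COLONOSCOPY = "COLONOSCOPY"
    POLYPECTOMY = "POLYPECTOMY"
    CRC_SURGERY = "CRC_SURGERY"
    ADJUVANT_CHEMO_III = "ADJUVANT_CHEMO_III"
    SYSTEMIC_CHEMO_IV = "SYSTEMIC_CHEMO_IV"
    FOLLOWUP_STAGE_I = "FOLLOWUP_STAGE_I"
    FOLLOWUP_STAGE_I_II = "FOLLOWUP_STAGE_I_II"


class StateUtilityGroup(str, enum.Enum):
    HEALTHY = "HEALTHY"
    ADENOMA = "ADENOMA"
    CRC_I_II = "CRC_I_II"
    CRC_III = "CRC_III"
    CRC_IV = "CRC_IV"


HEALTHY = "HEALTHY"  # key used alongside LesionClass members in distributions


@dataclass
class InitialDistribution:
    """Health-state mix of the cohort at model entry (index colonoscopy)."""

    probabilities: dict  # {HEALTHY | LesionClass: proportion}
    population_label: PopulationLabel = PopulationLabel.FIT_POSITIVE

    def __getitem__(self, key):
        return self.probabilities[key]

    def total(self) -> float:
        return float(sum(self.probabilities.values()))


@dataclass
class DetectionParams:
    """Colonoscopy miss rates and the CADe effect measures.

    ``amr_conventional`` holds the per-size adenoma miss rates of
    unassisted colonoscopy; the conventional CRC I/II miss rate is the
    large-adenoma AMR times ``crc_amr_halving_factor``.  The CADe arm's
    miss rates come either from the tabulated AI-aided detection rates
    (``DIRECT_TABLE``, default) or from dividing the conventional miss
    rate by the per-class incidence-rate ratio (``IRR_DERIVED``).
    """

    amr_conventional: dict = field(default_factory=dict)  # LesionClass -> CI
    irr: dict = field(default_factory=dict)               # LesionClass -> CI
    cade_miss_mode: CadeMissMode = CadeMissMode.DIRECT_TABLE
    cade_miss_direct: dict = field(default_factory=dict)  # LesionClass -> float
    crc_amr_halving_factor: float = 0.5


@dataclass
class NaturalHistoryParams:
    onset_by_age: list = field(default_factory=list)  # [(age, CI), ...]
    progression: dict = field(default_factory=dict)   # transition name -> CI
    recurrence_rate: dict = field(default_factory=dict)  # LesionClass(CRC) -> float
    crc_mortality: dict = field(default_factory=dict)
    # crc_mortality keys: (stage_group "I_II"|"III_IV", band "<65"|"65-75"|"75+",
    #                      recurrence bool) -> annual probability
    presentation_rate: dict = field(default_factory=dict)  # LesionClass(CRC) -> float
    # annual probability that undetected CRC presents clinically between
    # scheduled tests and is diagnosed and treated


PROGRESSION_KEYS = (
    "small_to_medium",
    "medium_to_large",
    "large_to_crc_i",
    "crc_i_to_ii",
    "crc_ii_to_iii",
    "crc_iii_to_iv",
)


@dataclass
class UtilityParams:
    utility: dict = field(default_factory=dict)  # StateUtilityGroup -> CI


@dataclass
class EconomicParams:
    cost: dict = field(default_factory=dict)  # CostItem -> (base, dsa_high)
    device_monthly_fee: float = 2250.0
    annual_colonoscopy_volume: float = 1000.0
    contract_years: float = 3.0
    discount_rate: float = 0.035
    wtp: float = 50_000.0

    def base_cost(self, item: CostItem) -> float:
        return self.cost[item][0]

    def device_cost_per_procedure(self) -> float:
        """Monthly subscription amortised over the yearly procedure volume."""
        return self.device_monthly_fee * 12.0 / self.annual_colonoscopy_volume


@dataclass
class LifeTable:
    """Background all-cause mortality: annual death probability by age."""

    qx: dict = field(default_factory=dict)  # int age -> probability

    def prob(self, age: float) -> float:
        a = int(age)
        if a in self.qx:
            return self.qx[a]
        ages = sorted(self.qx)
        if not ages:
            raise ValueError("empty life table")
        if a < ages[0]:
            return self.qx[ages[0]]
        return self.qx[ages[-1]]

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        qx = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.lower().startswith("age"):
                    continue
                a, q = line.split(",")[:2]
                qx[int(float(a))] = float(q)
        return cls(qx=qx)

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("age,qx\n")
            for a in sorted(self.qx):
                fh.write(f"{a},{self.qx[a]!r}\n")


@dataclass
class SurveillancePolicy:
    """Guideline follow-up intervals after an index/surveillance test."""

    negative_fit_interval: int = 10  # negative colonoscopy -> FIT in 10 y
    low_risk_interval: int = 5       # small/medium adenoma -> colonoscopy in 5 y
    high_risk_interval: int = 3      # large adenoma -> colonoscopy in 3 y
    fit_screening_interval: int = 2  # negative FIT -> routine biennial FIT


@dataclass
class ScenarioConfig:
    start_age: int = 50
    max_age: int = 100
    male_fraction: float = 0.545
    initial: InitialDistribution = None
    detection: DetectionParams = None
    natural_history: NaturalHistoryParams = None
    utilities: UtilityParams = None
    economics: EconomicParams = None
    life_table: LifeTable = None
    surveillance: SurveillancePolicy = field(default_factory=SurveillancePolicy)
    half_cycle_correction: bool = True
    fit_sensitivity: float = 0.75


# ---------------------------------------------------------------------------
# Packaged defaults (base-case parameter set)
# ---------------------------------------------------------------------------

#: FIT-positive initial distribution (sums to 1.0000 exactly as printed).
_INITIAL_FIT_POSITIVE = {
    HEALTHY: 0.4043,
    LesionClass.ADENOMA_SMALL: 0.3400,
    LesionClass.ADENOMA_MEDIUM: 0.1064,
    LesionClass.ADENOMA_LARGE: 0.1043,
    LesionClass.CRC_I: 0.0237,
    LesionClass.CRC_II: 0.0090,
    LesionClass.CRC_III: 0.0123,
    LesionClass.CRC_IV: 0.0000,
}

# The published screening column sums to 1.0001; it is renormalised by its
# own total so the distribution invariant holds exactly.
_INITIAL_SCREENING_RAW = {
    HEALTHY: 0.9756,
    LesionClass.ADENOMA_SMALL: 0.0139,
    LesionClass.ADENOMA_MEDIUM: 0.0044,
    LesionClass.ADENOMA_LARGE: 0.0043,
    LesionClass.CRC_I: 0.0010,
    LesionClass.CRC_II: 0.0004,
    LesionClass.CRC_III: 0.0005,
    LesionClass.CRC_IV: 0.0000,
}

_CRC_IRR = CI(3.36, 0.93, 12.11)  # per-patient CRC detection-rate ratio, used as proxy

_DEFAULT_AMR = {
    LesionClass.ADENOMA_SMALL: CI(0.31, 0.25, 0.38),
    LesionClass.ADENOMA_MEDIUM: CI(0.19, 0.12, 0.28),
    LesionClass.ADENOMA_LARGE: CI(0.09, 0.04, 0.16),
}

_DEFAULT_IRR = {
    LesionClass.ADENOMA_SMALL: CI(1.64, 1.24, 2.18),
    LesionClass.ADENOMA_MEDIUM: CI(1.64, 1.24, 2.18),
    LesionClass.ADENOMA_LARGE: CI(1.07, 0.66, 1.74),
    LesionClass.CRC_I: _CRC_IRR,
    LesionClass.CRC_II: _CRC_IRR,
    LesionClass.CRC_III: _CRC_IRR,
    LesionClass.CRC_IV: _CRC_IRR,
}

# AI-aided miss rates: adenomas from the published detection-rate table;
# CRC I/II from dividing the conventional 4.5% miss by the CRC rate ratio.
_DEFAULT_CADE_MISS = {
    LesionClass.ADENOMA_SMALL: 0.1726,
    LesionClass.ADENOMA_MEDIUM: 0.0828,
    LesionClass.ADENOMA_LARGE: 0.0760,
    LesionClass.CRC_I: 0.09 * 0.5 / 3.36,
    LesionClass.CRC_II: 0.09 * 0.5 / 3.36,
}

_DEFAULT_ONSET = [
    (50, CI(0.008, 0.004, 0.017)),
    (55, CI(0.010, 0.005, 0.020)),
    (60, CI(0.012, 0.006, 0.023)),
    (65, CI(0.013, 0.007, 0.027)),
    (70, CI(0.015, 0.008, 0.030)),
]

_DEFAULT_PROGRESSION = {
    "small_to_medium": CI(0.035, 0.017, 0.069),
    "medium_to_large": CI(0.022, 0.011, 0.043),
    "large_to_crc_i": CI(0.370, 0.268, 0.472),
    "crc_i_to_ii": CI(0.238, 0.206, 0.271),
    "crc_ii_to_iii": CI(0.485, 0.321, 0.650),
    "crc_iii_to_iv": CI(0.302, 0.151, 0.604),
}

#: Annual symptomatic-presentation probabilities of undetected CRC between
#: scheduled tests (cancers are assessed every cycle, not only at the next
#: surveillance test).  No source prints these; they are documented model
#: constants rising with stage, consistent with the short pre-clinical
#: sojourn of advanced disease.
_DEFAULT_PRESENTATION = {
    LesionClass.CRC_I: 0.20,
    LesionClass.CRC_II: 0.40,
    LesionClass.CRC_III: 0.70,
    LesionClass.CRC_IV: 0.90,
}

_DEFAULT_RECURRENCE = {
    LesionClass.CRC_I: 0.058,
    LesionClass.CRC_II: 0.058,
    LesionClass.CRC_III: 0.188,
    LesionClass.CRC_IV: 0.188,
}

_DEFAULT_CRC_MORTALITY = {
    ("I_II", "<65", False): 0.030,
    ("I_II", "65-75", False): 0.050,
    ("I_II", "75+", False): 0.105,
    ("III_IV", "<65", False): 0.050,
    ("III_IV", "65-75", False): 0.085,
    ("III_IV", "75+", False): 0.165,
    ("I_II", "<65", True): 0.560,
    ("I_II", "65-75", True): 0.560,
    ("I_II", "75+", True): 0.870,
    ("III_IV", "<65", True): 0.680,
    ("III_IV", "65-75", True): 0.670,
    ("III_IV", "75+", True): 0.935,
}

#: Healthy-state utility: the source prints no value; 0.90 is a documented
#: calibration constant consistent with general-population utility norms at
#: ages 50+ (see docs/methods.md).  The clinical-state utilities are the
#: published means and 95% CIs.
HEALTHY_UTILITY_DEFAULT = 0.90

_DEFAULT_UTILITIES = {
    StateUtilityGroup.HEALTHY: CI(HEALTHY_UTILITY_DEFAULT),
    StateUtilityGroup.ADENOMA: CI(0.91, 0.87, 0.93),
    StateUtilityGroup.CRC_I_II: CI(0.67, 0.62, 0.72),
    StateUtilityGroup.CRC_III: CI(0.59, 0.54, 0.69),
    StateUtilityGroup.CRC_IV: CI(0.25, 0.20, 0.31),
}

# (base cost, published +15% DSA bound), 2022 CAD.  The +15% column is
# stored verbatim rather than recomputed, to preserve the printed values.
_DEFAULT_COSTS = {
    CostItem.FIT: (31.11, 35.77),
    CostItem.COLONOSCOPY: (688.00, 791.20),
    CostItem.POLYPECTOMY: (413.00, 474.95),
    CostItem.CRC_SURGERY: (12_082.00, 13_894.30),
    CostItem.ADJUVANT_CHEMO_III: (9_637.00, 11_082.00),
    CostItem.SYSTEMIC_CHEMO_IV: (11_442.00, 13_158.30),
    CostItem.FOLLOWUP_STAGE_I: (306.00, 351.90),
    CostItem.FOLLOWUP_STAGE_I_II: (1_427.85, 1_642.14),
}


def default_scenario(population: PopulationLabel = PopulationLabel.FIT_POSITIVE) -> ScenarioConfig:
    """The packaged base-case parameter set (FIT-positive cohort, age 50+)."""
    from . import synthetic  # local import; synthetic depends on these types

    if population == PopulationLabel.FIT_POSITIVE:
        probs = dict(_INITIAL_FIT_POSITIVE)
    else:
        total = sum(_INITIAL_SCREENING_RAW.values())
        probs = {k: v / total for k, v in _INITIAL_SCREENING_RAW.items()}
    return ScenarioConfig(
        start_age=50,
        max_age=100,
        male_fraction=0.545,
        initial=InitialDistribution(probabilities=probs, population_label=population),
        detection=DetectionParams(
            amr_conventional=copy.deepcopy(_DEFAULT_AMR),
            irr=copy.deepcopy(_DEFAULT_IRR),
            cade_miss_mode=CadeMissMode.DIRECT_TABLE,
            cade_miss_direct=dict(_DEFAULT_CADE_MISS),
            crc_amr_halving_factor=0.5,
        ),
        natural_history=NaturalHistoryParams(
            onset_by_age=list(_DEFAULT_ONSET),
            progression=copy.deepcopy(_DEFAULT_PROGRESSION),
            recurrence_rate=dict(_DEFAULT_RECURRENCE),
            crc_mortality=dict(_DEFAULT_CRC_MORTALITY),
            presentation_rate=dict(_DEFAULT_PRESENTATION),
        ),
        utilities=UtilityParams(utility=copy.deepcopy(_DEFAULT_UTILITIES)),
        economics=EconomicParams(cost=dict(_DEFAULT_COSTS)),
        life_table=synthetic.generate_life_table(),
        surveillance=SurveillancePolicy(),
        half_cycle_correction=True,
        fit_sensitivity=0.75,
    )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

@dataclass
class Violation:
    field: str
    value: object
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field} = {self.value!r} violates: {self.rule}"


class ScenarioValidationError(ValueError):
    def __init__(self, violations: list):
        self.violations = violations
        super().__init__(
            "invalid scenario configuration:\n" + "\n".join(str(v) for v in violations)
        )


def _iter_probability_fields(cfg: ScenarioConfig) -> Iterator[tuple[str, float]]:
    for k, v in cfg.initial.probabilities.items():
        yield f"initial.probabilities[{getattr(k, 'name', k)}]", v
    for c, ci in cfg.detection.amr_conventional.items():
        for tag, x in zip(("mean", "lo", "hi"), ci):
            yield f"detection.amr_conventional[{c.name}].{tag}", x
    for c, p in cfg.detection.cade_miss_direct.items():
        yield f"detection.cade_miss_direct[{c.name}]", p
    for age, ci in cfg.natural_history.onset_by_age:
        yield f"natural_history.onset_by_age[{age}]", ci.mean
    for name, ci in cfg.natural_history.progression.items():
        for tag, x in zip(("mean", "lo", "hi"), ci):
            yield f"natural_history.progression[{name}].{tag}", x
    for c, p in cfg.natural_history.recurrence_rate.items():
        yield f"natural_history.recurrence_rate[{c.name}]", p
    for key, p in cfg.natural_history.crc_mortality.items():
        yield f"natural_history.crc_mortality[{key}]", p
    for c, p in cfg.natural_history.presentation_rate.items():
        yield f"natural_history.presentation_rate[{c.name}]", p
    yield "fit_sensitivity", cfg.fit_sensitivity
    yield "detection.crc_amr_halving_factor", cfg.detection.crc_amr_halving_factor


def validate(cfg: ScenarioConfig) -> list:
    """Check every type invariant; violations are returned, not raised."""
    v: list[Violation] = []

    total = cfg.initial.total()
    if abs(total - 1.0) > 1e-9:
        v.append(Violation("initial.probabilities", total, "proportions must sum to 1"))
    for name, p in _iter_probability_fields(cfg):
        if not (0.0 <= p <= 1.0):
            v.append(Violation(name, p, "probability must lie in [0, 1]"))
    for c, ci in cfg.detection.irr.items():
        if ci.mean <= 0:
            v.append(Violation(f"detection.irr[{c.name}].mean", ci.mean, "IRR mean must be > 0"))
        if not (ci.lo <= ci.mean <= ci.hi):
            v.append(Violation(f"detection.irr[{c.name}]", tuple(ci), "requires lo <= mean <= hi"))
    for g, ci in cfg.utilities.utility.items():
        if not (0.0 <= ci.mean <= 1.0):
            v.append(Violation(f"utilities.utility[{g.value}].mean", ci.mean, "utility must lie in [0, 1]"))
        if not (ci.lo <= ci.mean <= ci.hi):
            v.append(Violation(f"utilities.utility[{g.value}]", tuple(ci), "requires lo <= mean <= hi"))
    for item, (base, hi) in cfg.economics.cost.items():
        if base < 0 or hi < 0:
            v.append(Violation(f"economics.cost[{item.value}]", (base, hi), "costs must be >= 0"))
    if not (0.0 <= cfg.economics.discount_rate < 1.0):
        v.append(Violation("economics.discount_rate", cfg.economics.discount_rate, "discount rate must lie in [0, 1)"))
    if cfg.economics.wtp <= 0:
        v.append(Violation("economics.wtp", cfg.economics.wtp, "willingness-to-pay must be > 0"))
    if not cfg.start_age < cfg.max_age:
        v.append(Violation("start_age", cfg.start_age, "requires start_age < max_age"))
    for name in ("negative_fit_interval", "low_risk_interval", "high_risk_interval",
                 "fit_screening_interval"):
        iv = getattr(cfg.surveillance, name)
        if iv < 1:
            v.append(Violation(f"surveillance.{name}", iv, "interval must be >= 1 year"))
    ages = [a for a, _ in cfg.natural_history.onset_by_age]
    if ages != sorted(set(ages)):
        v.append(Violation("natural_history.onset_by_age", ages, "ages must be strictly increasing"))
    for a, q in cfg.life_table.qx.items():
        if not (0.0 <= q <= 1.0):
            v.append(Violation(f"life_table.qx[{a}]", q, "probability must lie in [0, 1]"))
    lt_ages = sorted(cfg.life_table.qx)
    if lt_ages and (lt_ages[0] > cfg.start_age or lt_ages[-1] < cfg.max_age):
        v.append(Violation("life_table.qx", (lt_ages[0], lt_ages[-1]),
                           "life table must cover [start_age, max_age]"))
    above60 = [cfg.life_table.qx[a] for a in lt_ages if a >= 60]
    if any(b < a - 1e-12 for a, b in zip(above60, above60[1:])):
        v.append(Violation("life_table.qx", "non-monotone", "qx must be non-decreasing above age 60"))
    return v


# ---------------------------------------------------------------------------
# Scenario file I/O (YAML dialect)
# ---------------------------------------------------------------------------

def _ci_to_list(ci: CI) -> list:
    return [ci.mean, ci.lo, ci.hi]


def scenario_to_dict(cfg: ScenarioConfig) -> dict:
    """Plain-dict form of a configuration (the YAML schema)."""
    return {
        "start_age": cfg.start_age,
        "max_age": cfg.max_age,
        "male_fraction": cfg.male_fraction,
        "half_cycle_correction": cfg.half_cycle_correction,
        "fit_sensitivity": cfg.fit_sensitivity,
        "initial": {
            "population_label": cfg.initial.population_label.value,
            "probabilities": {getattr(k, "name", k): v for k, v in cfg.initial.probabilities.items()},
        },
        "detection": {
            "amr_conventional": {c.name: _ci_to_list(ci) for c, ci in cfg.detection.amr_conventional.items()},
            "irr": {c.name: _ci_to_list(ci) for c, ci in cfg.detection.irr.items()},
            "cade_miss_mode": cfg.detection.cade_miss_mode.value,
            "cade_miss_direct": {c.name: p for c, p in cfg.detection.cade_miss_direct.items()},
            "crc_amr_halving_factor": cfg.detection.crc_amr_halving_factor,
        },
        "natural_history": {
            "onset_by_age": [[a, _ci_to_list(ci)] for a, ci in cfg.natural_history.onset_by_age],
            "progression": {k: _ci_to_list(ci) for k, ci in cfg.natural_history.progression.items()},
            "recurrence_rate": {c.name: p for c, p in cfg.natural_history.recurrence_rate.items()},
            "presentation_rate": {c.name: p for c, p in cfg.natural_history.presentation_rate.items()},
            "crc_mortality": {f"{g}|{b}|{'rec' if r else 'norec'}": p
                              for (g, b, r), p in cfg.natural_history.crc_mortality.items()},
        },
        "utilities": {g.value: _ci_to_list(ci) for g, ci in cfg.utilities.utility.items()},
        "economics": {
            "cost": {item.value: list(pair) for item, pair in cfg.economics.cost.items()},
            "device_monthly_fee": cfg.economics.device_monthly_fee,
            "annual_colonoscopy_volume": cfg.economics.annual_colonoscopy_volume,
            "contract_years": cfg.economics.contract_years,
            "discount_rate": cfg.economics.discount_rate,
            "wtp": cfg.economics.wtp,
        },
        "surveillance": dataclasses.asdict(cfg.surveillance),
        "life_table": {"qx": {int(a): float(q) for a, q in sorted(cfg.life_table.qx.items())}},
    }


def _lesion_key(name: str):
    return LesionClass[name] if name in LesionClass.__members__ else name


def scenario_from_dict(d: dict, base: ScenarioConfig | None = None) -> ScenarioConfig:
    """Build a configuration from a (possibly partial) plain dict.

    Missing fields fall back to the packaged defaults (or to ``base``);
    every override relative to the fallback is logged.
    """
    cfg = copy.deepcopy(base) if base is not None else default_scenario()
    d = d or {}

    for key in ("start_age", "max_age", "male_fraction", "half_cycle_correction", "fit_sensitivity"):
        if key in d:
            logger.info("scenario override: %s = %r", key, d[key])
            setattr(cfg, key, d[key])
    if "initial" in d:
        sub = d["initial"]
        if "population_label" in sub:
            cfg.initial.population_label = PopulationLabel(sub["population_label"])
        if "probabilities" in sub:
            cfg.initial.probabilities = {_lesion_key(k): float(v) for k, v in sub["probabilities"].items()}
        logger.info("scenario override: initial = %r", sub)
    if "detection" in d:
        sub = d["detection"]
        det = cfg.detection
        if "amr_conventional" in sub:
            det.amr_conventional = {LesionClass[k]: CI(*v) for k, v in sub["amr_conventional"].items()}
        if "irr" in sub:
            det.irr = {LesionClass[k]: CI(*v) for k, v in sub["irr"].items()}
        if "cade_miss_mode" in sub:
            det.cade_miss_mode = CadeMissMode(sub["cade_miss_mode"])
        if "cade_miss_direct" in sub:
            det.cade_miss_direct = {LesionClass[k]: float(v) for k, v in sub["cade_miss_direct"].items()}
        if "crc_amr_halving_factor" in sub:
            det.crc_amr_halving_factor = float(sub["crc_amr_halving_factor"])
        logger.info("scenario override: detection = %r", sub)
    if "natural_history" in d:
        sub = d["natural_history"]
        nh = cfg.natural_history
        if "onset_by_age" in sub:
            nh.onset_by_age = [(int(a), CI(*ci)) for a, ci in sub["onset_by_age"]]
        if "progression" in sub:
            nh.progression = {k: CI(*v) for k, v in sub["progression"].items()}
        if "recurrence_rate" in sub:
            nh.recurrence_rate = {LesionClass[k]: float(v) for k, v in sub["recurrence_rate"].items()}
        if "presentation_rate" in sub:
            nh.presentation_rate = {LesionClass[k]: float(v) for k, v in sub["presentation_rate"].items()}
        if "crc_mortality" in sub:
            mort = {}
            for key, p in sub["crc_mortality"].items():
                g, b, r = key.split("|")
                mort[(g, b, r == "rec")] = float(p)
            nh.crc_mortality = mort
        logger.info("scenario override: natural_history = %r", sub)
    if "utilities" in d:
        cfg.utilities = UtilityParams(
            utility={StateUtilityGroup(k): CI(*v) for k, v in d["utilities"].items()}
        )
        logger.info("scenario override: utilities = %r", d["utilities"])
    if "economics" in d:
        sub = d["economics"]
        eco = cfg.economics
        if "cost" in sub:
            eco.cost = {CostItem(k): tuple(float(x) for x in v) for k, v in sub["cost"].items()}
        for key in ("device_monthly_fee", "annual_colonoscopy_volume", "contract_years",
                    "discount_rate", "wtp"):
            if key in sub:
                setattr(eco, key, float(sub[key]))
        logger.info("scenario override: economics = %r", sub)
    if "surveillance" in d:
        for key, val in d["surveillance"].items():
            setattr(cfg.surveillance, key, int(val))
        logger.info("scenario override: surveillance = %r", d["surveillance"])
    if "life_table" in d:
        sub = d["life_table"]
        if "csv" in sub:
            cfg.life_table = LifeTable.from_csv(sub["csv"])
        elif "qx" in sub:
            cfg.life_table = LifeTable(qx={int(a): float(q) for a, q in sub["qx"].items()})
        logger.info("scenario override: life_table (%d ages)", len(cfg.life_table.qx))
    return cfg


def load_scenario(path, base: ScenarioConfig | None = None) -> ScenarioConfig:
    """Read and validate a YAML scenario file; raise on any violation."""
    with open(path) as fh:
        try:
            d = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"cannot parse scenario file {path}: {exc}") from exc
    cfg = scenario_from_dict(d or {}, base=base)
    violations = validate(cfg)
    if violations:
        raise ScenarioValidationError(violations)
    return cfg


def write_scenario(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(scenario_to_dict(cfg), fh, sort_keys=False)
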
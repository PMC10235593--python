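"""Deterministic (tornado) and probabilistic sensitivity analyses.

The DSA moves one parameter at a time to its published low/high bound
(costs: -15% computed, +15% as printed) and records the incremental net
monetary benefit of CADe at the configured willingness-to-pay; rows are
sorted by outcome spread, tornado-style.

The PSA draws independent parameter sets — Beta for probabilities and
utilities (moment-matched to mean and 95% CI), Gamma for costs (±15%
read as a 95% interval), Lognormal for rate ratios (median at the point
estimate, log-width from the CI) — reruns both arms per draw, and
summarises the joint (ΔCost, ΔQALY) cloud as a cost-effectiveness plane,
a CEAC, and the acceptability fraction at the configured threshold.  The
detection-improving scenario truncates the IRR draws at 1 using the same
underlying uniforms, so a paired run differs only in the removed
unfavourable tail.
"""

from __future__ import annotations

import copy
import enum
import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import run_arm
from .detection import cade_detection, conventional_detection, crc_miss_rates
from .economics import CEResult, compare
from .params import (
    CI,
    ADENOMA_CLASSES,
    CostItem,
    LesionClass,
    ScenarioConfig,
    StateUtilityGroup,
    validate,
)

logger = logging.getLogger(__name__)

__all__ = ["DsaRow", "DsaParameter", "default_dsa_ranges", "run_dsa",
           "IrrTruncation", "PsaSpec", "PsaResult", "draw_parameters", "run_psa"]


# ---------------------------------------------------------------------------
# Deterministic sensitivity analysis
# ---------------------------------------------------------------------------

@dataclass
class DsaParameter:
    name: str
    low: float
    high: float
    setter: object  # callable (ScenarioConfig, float) -> None, mutates in place


@dataclass
class DsaRow:
    parameter: str
    low: float
    high: float
    nmb_at_low: float
    nmb_at_high: float
    icer_label_low: object
    icer_label_high: object

    @property
    def spread(self) -> float:
        return abs(self.nmb_at_high - self.nmb_at_low)


def _set_amr(cfg: ScenarioConfig, lesion: LesionClass, value: float) -> None:
    cfg.detection.amr_conventional[lesion] = CI(value)
    if lesion == LesionClass.ADENOMA_LARGE:
        # the CADe CRC I/II miss rate is derived from the conventional one
        crc = crc_miss_rates(value, cfg.detection.crc_amr_halving_factor)
        for c in (LesionClass.CRC_I, LesionClass.CRC_II):
            if c in cfg.detection.cade_miss_direct:
                cfg.detection.cade_miss_direct[c] = min(
                    1.0, crc / cfg.detection.irr[c].mean)


def _ci_at(mean: float, template: CI) -> CI:
    """A CI centred on ``mean`` keeping the template bounds (widened if needed)."""
    return CI(mean, min(mean, template.lo), max(mean, template.hi))


def _set_irr(cfg: ScenarioConfig, classes: tuple, base_irr: dict,
             base_direct: dict, value: float) -> None:
    for c in classes:
        cfg.detection.irr[c] = _ci_at(value, base_irr[c])
        if c in base_direct:
            cfg.detection.cade_miss_direct[c] = min(
                1.0, max(0.0, base_direct[c] * base_irr[c].mean / value))


def _set_utility(cfg: ScenarioConfig, group: StateUtilityGroup, value: float) -> None:
    cfg.utilities.utility[group] = CI(value)


def _set_progression(cfg: ScenarioConfig, key: str, value: float) -> None:
    cfg.natural_history.progression[key] = CI(value)


def _set_onset_scale(cfg: ScenarioConfig, frac: float) -> None:
    """Move every onset knot a fraction of the way to its lo (-1) / hi (+1)."""
    new = []
    for age, ci in cfg.natural_history.onset_by_age:
        if frac >= 0:
            val = ci.mean + frac * (ci.hi - ci.mean)
        else:
            val = ci.mean + frac * (ci.mean - ci.lo)
        new.append((age, CI(val)))
    cfg.natural_history.onset_by_age = new


def _set_cost(cfg: ScenarioConfig, item: CostItem, value: float) -> None:
    _, hi = cfg.economics.cost[item]
    cfg.economics.cost[item] = (value, hi)


def _set_device_fee(cfg: ScenarioConfig, value: float) -> None:
    cfg.economics.device_monthly_fee = value


def default_dsa_ranges(config: ScenarioConfig) -> list:
    """The published one-way ranges: effect-measure CIs and cost bounds."""
    det = config.detection
    base_irr = dict(det.irr)
    base_direct = dict(det.cade_miss_direct)
    params: list[DsaParameter] = []
    size_name = {LesionClass.ADENOMA_SMALL: "small adenoma",
                 LesionClass.ADENOMA_MEDIUM: "medium adenoma",
                 LesionClass.ADENOMA_LARGE: "large adenoma"}
    for c in ADENOMA_CLASSES:
        ci = det.amr_conventional[c]
        params.append(DsaParameter(
            f"AMR {size_name[c]}", ci.lo, ci.hi,
            lambda cfg, v, c=c: _set_amr(cfg, c, v)))
    irr_groups = [
        ("IRR small adenoma", (LesionClass.ADENOMA_SMALL,)),
        ("IRR medium adenoma", (LesionClass.ADENOMA_MEDIUM,)),
        ("IRR large adenoma", (LesionClass.ADENOMA_LARGE,)),
        ("IRR CRC", (LesionClass.CRC_I, LesionClass.CRC_II,
                     LesionClass.CRC_III, LesionClass.CRC_IV)),
    ]
    for name, classes in irr_groups:
        ci = det.irr[classes[0]]
        params.append(DsaParameter(
            name, ci.lo, ci.hi,
            lambda cfg, v, cls=classes: _set_irr(cfg, cls, base_irr, base_direct, v)))
    util_name = {StateUtilityGroup.ADENOMA: "Utility adenoma",
                 StateUtilityGroup.CRC_I_II: "Utility CRC I-II",
                 StateUtilityGroup.CRC_III: "Utility CRC III",
                 StateUtilityGroup.CRC_IV: "Utility CRC IV"}
    for g, name in util_name.items():
        ci = config.utilities.utility[g]
        params.append(DsaParameter(
            name, ci.lo, ci.hi, lambda cfg, v, g=g: _set_utility(cfg, g, v)))
    for key, ci in config.natural_history.progression.items():
        params.append(DsaParameter(
            f"Transition {key.replace('_', ' ')}", ci.lo, ci.hi,
            lambda cfg, v, k=key: _set_progression(cfg, k, v)))
    params.append(DsaParameter("Adenoma onset rate", -1.0, 1.0, _set_onset_scale))
    for item, (base, hi) in config.economics.cost.items():
        params.append(DsaParameter(
            f"Cost {item.value}", 0.85 * base, hi,
            lambda cfg, v, it=item: _set_cost(cfg, it, v)))
    fee = config.economics.device_monthly_fee
    params.append(DsaParameter("Cost device subscription", 0.85 * fee, 1.15 * fee,
                               _set_device_fee))
    return params


def _incremental(config: ScenarioConfig, wtp: float | None = None) -> CEResult:
    wtp = config.economics.wtp if wtp is None else wtp
    conv = run_arm(config, conventional_detection(config.detection))
    cade = run_arm(config, cade_detection(config.detection))
    return compare(conv, cade, wtp)


def run_dsa(config: ScenarioConfig, ranges: list | None = None,
            wtp: float | None = None) -> list:
    """One-way DSA; rows sorted by |NMB(high) - NMB(low)| descending."""
    ranges = default_dsa_ranges(config) if ranges is None else ranges
    rows: list[DsaRow] = []
    for p in ranges:
        outcomes = []
        ok = True
        for value in (p.low, p.high):
            cfg = copy.deepcopy(config)
            p.setter(cfg, value)
            violations = validate(cfg)
            if violations:
                logger.warning("DSA range for %s at %s violates invariants; skipped: %s",
                               p.name, value, "; ".join(map(str, violations)))
                ok = False
                break
            outcomes.append(_incremental(cfg, wtp))
        if not ok:
            continue
        lo, hi = outcomes
        rows.append(DsaRow(p.name, p.low, p.high, lo.nmb, hi.nmb,
                           lo.icer_per_qaly, hi.icer_per_qaly))
    rows.sort(key=lambda r: r.spread, reverse=True)
    return rows


# ---------------------------------------------------------------------------
# Probabilistic sensitivity analysis
# ---------------------------------------------------------------------------

class IrrTruncation(str, enum.Enum):
    FULL_CI = "FULL_CI"
    POSITIVE_ONLY = "POSITIVE_ONLY"


@dataclass
class PsaSpec:
    n_draws: int = 1000
    seed: int = 0
    irr_truncation: IrrTruncation = IrrTruncation.FULL_CI
    wtp_grid: tuple = tuple(range(0, 100_001, 5_000))
    variance_scale: float = 1.0  # 0 collapses every distribution to its mean


@dataclass
class PsaResult:
    draws: np.ndarray            # (n, 2): delta_cost, delta_qaly
    ceac: dict                   # wtp -> acceptability fraction
    fraction_ce_at_wtp: float
    wtp: float
    n_failed: int = 0

    def acceptability(self, wtp: float) -> float:
        dc, dq = self.draws[:, 0], self.draws[:, 1]
        return float(np.mean(wtp * dq - dc > 0))


def _beta_from_ci(ci: CI, scale: float):
    sd = scale * (ci.hi - ci.lo) / (2 * 1.959964)
    if sd == 0.0:
        return None
    m = ci.mean
    if not 0.0 < m < 1.0:
        raise ValueError(f"Beta family needs mean in (0,1), got {m}")
    nu = m * (1 - m) / sd**2 - 1.0
    if nu <= 0:
        raise ValueError(f"CI {tuple(ci)} inconsistent with Beta support")
    return stats.beta(m * nu, (1 - m) * nu)


def _gamma_pm15(mean: float, scale: float):
    sd = scale * 0.15 * mean / 1.959964
    if sd == 0.0 or mean == 0.0:
        return None
    k = (mean / sd) ** 2
    return stats.gamma(k, scale=sd**2 / mean)


def _lognorm_params(ci: CI, scale: float):
    sigma = scale * (np.log(ci.hi) - np.log(ci.lo)) / (2 * 1.959964)
    return ci.mean, sigma


def _draw_lognorm(u: float, mean: float, sigma: float, truncate_at_one: bool) -> float:
    if sigma == 0.0:
        return mean
    mu = np.log(mean)
    if truncate_at_one:
        f1 = stats.norm.cdf((0.0 - mu) / sigma)  # ln(1) = 0
        u = f1 + u * (1.0 - f1)
    return float(np.exp(mu + sigma * stats.norm.ppf(u)))


def draw_parameters(spec: PsaSpec, base: ScenarioConfig):
    """Yield ``spec.n_draws`` independent sampled configurations.

    Sampling consumes one uniform per parameter in a fixed order, so runs
    with the same seed are paired draw-by-draw across truncation modes.
    """
    rng = np.random.default_rng(spec.seed)
    s = spec.variance_scale
    det0 = base.detection
    base_irr = {c: ci for c, ci in det0.irr.items()}
    base_direct = dict(det0.cade_miss_direct)
    truncate = spec.irr_truncation == IrrTruncation.POSITIVE_ONLY

    amr_dists = {c: _beta_from_ci(det0.amr_conventional[c], s) for c in ADENOMA_CLASSES}
    irr_params = {
        "small": _lognorm_params(det0.irr[LesionClass.ADENOMA_SMALL], s),
        "medium": _lognorm_params(det0.irr[LesionClass.ADENOMA_MEDIUM], s),
        "large": _lognorm_params(det0.irr[LesionClass.ADENOMA_LARGE], s),
        "crc": _lognorm_params(det0.irr[LesionClass.CRC_I], s),
    }
    util_dists = {g: _beta_from_ci(ci, s)
                  for g, ci in base.utilities.utility.items()
                  if not ci.is_degenerate()}
    prog_dists = {k: _beta_from_ci(ci, s)
                  for k, ci in base.natural_history.progression.items()}
    onset_dists = [(age, _beta_from_ci(ci, s))
                   for age, ci in base.natural_history.onset_by_age]
    cost_dists = {item: _gamma_pm15(pair[0], s)
                  for item, pair in base.economics.cost.items()}
    fee_dist = _gamma_pm15(base.economics.device_monthly_fee, s)

    def q(dist, fallback):
        u = rng.random()
        if dist is None:
            return fallback
        return float(dist.ppf(u))

    irr_class_of = {
        "small": (LesionClass.ADENOMA_SMALL,),
        "medium": (LesionClass.ADENOMA_MEDIUM,),
        "large": (LesionClass.ADENOMA_LARGE,),
        "crc": (LesionClass.CRC_I, LesionClass.CRC_II,
                LesionClass.CRC_III, LesionClass.CRC_IV),
    }

    for _ in range(spec.n_draws):
        cfg = copy.deepcopy(base)
        for c in ADENOMA_CLASSES:
            v = q(amr_dists[c], det0.amr_conventional[c].mean)
            cfg.detection.amr_conventional[c] = _ci_at(v, det0.amr_conventional[c])
        for name, (mean, sigma) in irr_params.items():
            v = _draw_lognorm(rng.random(), mean, sigma, truncate)
            _set_irr(cfg, irr_class_of[name], base_irr, base_direct, v)
        # CADe CRC I/II miss tracks both the drawn AMR and the drawn CRC IRR
        crc = crc_miss_rates(cfg.detection.amr_conventional[LesionClass.ADENOMA_LARGE].mean,
                             cfg.detection.crc_amr_halving_factor)
        for c in (LesionClass.CRC_I, LesionClass.CRC_II):
            if c in cfg.detection.cade_miss_direct:
                cfg.detection.cade_miss_direct[c] = min(1.0, crc / cfg.detection.irr[c].mean)
        for g, dist in util_dists.items():
            cfg.utilities.utility[g] = _ci_at(
                q(dist, base.utilities.utility[g].mean), base.utilities.utility[g])
        for k, dist in prog_dists.items():
            cfg.natural_history.progression[k] = _ci_at(
                q(dist, base.natural_history.progression[k].mean),
                base.natural_history.progression[k])
        cfg.natural_history.onset_by_age = [
            (age, _ci_at(q(dist, ci.mean), ci))
            for (age, dist), (_, ci) in zip(onset_dists, base.natural_history.onset_by_age)]
        for item, dist in cost_dists.items():
            v = q(dist, base.economics.cost[item][0])
            cfg.economics.cost[item] = (v, base.economics.cost[item][1])
        cfg.economics.device_monthly_fee = q(fee_dist, base.economics.device_monthly_fee)
        yield cfg


def run_psa(config: ScenarioConfig, spec: PsaSpec) -> PsaResult:
    """Monte Carlo PSA: rerun both arms per draw, summarise the CE plane."""
    draws = []
    failed = 0
    for i, cfg in enumerate(draw_parameters(spec, config)):
        try:
            res = _incremental(cfg)
            draws.append((res.delta_cost, res.delta_qaly))
        except Exception as exc:  # pragma: no cover - defensive
            failed += 1
            logger.warning("PSA draw %d failed and was excluded: %s", i, exc)
    if failed > 0.01 * spec.n_draws:
        raise RuntimeError(f"{failed} of {spec.n_draws} PSA draws failed")
    arr = np.asarray(draws, dtype=float)
    dc, dq = arr[:, 0], arr[:, 1]
    ceac = {float(w): float(np.mean(w * dq - dc > 0)) for w in spec.wtp_grid}
    wtp = config.economics.wtp
    return PsaResult(
        draws=arr,
        ceac=ceac,
        fraction_ce_at_wtp=float(np.mean(wtp * dq - dc > 0)),
        wtp=wtp,
        n_failed=failed,
    )
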
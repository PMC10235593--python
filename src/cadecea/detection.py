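"""Per-lesion-class colonoscopy sensitivity for each arm.

Colonoscopy sensitivity is one minus the miss rate.  The conventional arm
uses the published adenoma miss rates (AMR) by size; the CRC I/II miss
rate is the large-adenoma AMR reduced by a configurable factor (default
50%), and advanced CRC (stages III/IV) is assumed always detected at
colonoscopy.  The CADe arm either takes the published AI-aided rates
directly (default) or derives its miss rates by dividing the conventional
ones by the per-class incidence-rate ratio.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field

from .params import (
    ADENOMA_CLASSES,
    CadeMissMode,
    DetectionParams,
    LesionClass,
)

logger = logging.getLogger(__name__)

__all__ = ["Arm", "ArmDetection", "crc_miss_rates", "conventional_detection",
           "cade_detection", "rescale_cade_miss_for_irr"]


class Arm(str, enum.Enum):
    CONVENTIONAL = "CONVENTIONAL"
    CADE = "CADE"


@dataclass
class ArmDetection:
    arm: Arm
    miss_rate: dict = field(default_factory=dict)  # LesionClass -> probability

    @property
    def sensitivity(self) -> dict:
        return {c: 1.0 - m for c, m in self.miss_rate.items()}


def _clamp(p: float, label: str) -> float:
    if p < 0.0 or p > 1.0:
        logger.warning("clamping derived miss rate %s = %.6g into [0, 1]", label, p)
        return min(1.0, max(0.0, p))
    return p


def crc_miss_rates(amr_large: float, halving_factor: float) -> float:
    """Conventional CRC I/II miss rate: large-adenoma AMR times the factor."""
    if not 0.0 <= amr_large <= 1.0:
        raise ValueError(f"amr_large must lie in [0, 1], got {amr_large}")
    if not 0.0 <= halving_factor <= 1.0:
        raise ValueError(f"halving factor must lie in [0, 1], got {halving_factor}")
    return amr_large * halving_factor


def conventional_detection(params: DetectionParams) -> ArmDetection:
    """Miss rates of unassisted colonoscopy, all seven lesion classes."""
    miss = {c: params.amr_conventional[c].mean for c in ADENOMA_CLASSES}
    crc12 = crc_miss_rates(miss[LesionClass.ADENOMA_LARGE], params.crc_amr_halving_factor)
    miss[LesionClass.CRC_I] = crc12
    miss[LesionClass.CRC_II] = crc12
    # advanced CRC assumed symptomatic / always seen at colonoscopy
    miss[LesionClass.CRC_III] = 0.0
    miss[LesionClass.CRC_IV] = 0.0
    return ArmDetection(arm=Arm.CONVENTIONAL, miss_rate=miss)


def cade_detection(params: DetectionParams) -> ArmDetection:
    """Miss rates of AI-aided colonoscopy.

    ``DIRECT_TABLE`` (default): the configured direct per-class values,
    with CRC I/II falling back to conventional-miss / CRC-IRR when no
    direct value is configured.  ``IRR_DERIVED``: conventional miss
    divided by the per-class IRR mean.  Results are clamped to [0, 1].
    """
    conv = conventional_detection(params).miss_rate
    miss: dict = {}
    if params.cade_miss_mode == CadeMissMode.DIRECT_TABLE:
        for c in LesionClass:
            if c in params.cade_miss_direct:
                miss[c] = _clamp(float(params.cade_miss_direct[c]), c.name)
            elif c in (LesionClass.CRC_I, LesionClass.CRC_II):
                miss[c] = _clamp(conv[c] / params.irr[c].mean, c.name)
            else:
                miss[c] = conv[c]
    else:
        for c in LesionClass:
            irr = params.irr[c].mean
            if irr <= 0:
                raise ValueError(f"IRR for {c.name} must be > 0, got {irr}")
            miss[c] = _clamp(conv[c] / irr, c.name)
    return ArmDetection(arm=Arm.CADE, miss_rate=miss)


def rescale_cade_miss_for_irr(params: DetectionParams, baseline_irr: dict) -> None:
    """Make the direct CADe miss rates track a perturbed IRR, in place.

    Used by the sensitivity analyses: when an IRR is moved away from its
    baseline mean, the direct-table CADe miss rate for that class is
    scaled by (baseline IRR / new IRR), so a larger detection benefit
    lowers the miss rate proportionally and the baseline IRR reproduces
    the tabulated rates exactly.  Values are clamped to [0, 1].
    """
    for c, direct in list(params.cade_miss_direct.items()):
        base = baseline_irr[c].mean
        new = params.irr[c].mean
        if new <= 0:
            raise ValueError(f"IRR for {c.name} must be > 0, got {new}")
        params.cade_miss_direct[c] = min(1.0, max(0.0, direct * base / new))
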
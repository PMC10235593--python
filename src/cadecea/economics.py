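"""Between-arm comparison: incremental cost/effect, ICER, dominance, NMB."""

from __future__ import annotations

import json
from dataclasses import dataclass

from .cohort import ArmResult

__all__ = ["Dominance", "CEResult", "compare", "device_contract_cost"]


class Dominance:
    DOMINANT = "DOMINANT"      # comparator cheaper and more effective
    DOMINATED = "DOMINATED"    # comparator dearer and less effective
    EQUIVALENT = "EQUIVALENT"  # no cost or effect difference


@dataclass
class CEResult:
    delta_cost: float
    delta_ly: float
    delta_qaly: float
    icer_per_qaly: float | str
    icer_per_ly: float | str
    nmb: float
    wtp: float

    def to_dict(self) -> dict:
        return {
            "delta_cost": self.delta_cost,
            "delta_ly": self.delta_ly,
            "delta_qaly": self.delta_qaly,
            "icer_per_qaly": self.icer_per_qaly,
            "icer_per_ly": self.icer_per_ly,
            "nmb": self.nmb,
            "wtp": self.wtp,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def _icer(delta_cost: float, delta_effect: float) -> float | str:
    """ICER when cost and effect deltas share a sign; dominance label otherwise."""
    if delta_cost == 0.0 and delta_effect == 0.0:
        return Dominance.EQUIVALENT
    if delta_cost < 0.0 and delta_effect > 0.0:
        return Dominance.DOMINANT
    if delta_cost > 0.0 and delta_effect < 0.0:
        return Dominance.DOMINATED
    if delta_effect == 0.0:
        return Dominance.DOMINATED if delta_cost > 0 else Dominance.DOMINANT
    return delta_cost / delta_effect


def compare(reference: ArmResult, comparator: ArmResult, wtp: float) -> CEResult:
    """Incremental comparison of ``comparator`` against ``reference``."""
    dc = comparator.cost - reference.cost
    dly = comparator.ly - reference.ly
    dq = comparator.qaly - reference.qaly
    return CEResult(
        delta_cost=dc,
        delta_ly=dly,
        delta_qaly=dq,
        icer_per_qaly=_icer(dc, dq),
        icer_per_ly=_icer(dc, dly),
        nmb=wtp * dq - dc,
        wtp=wtp,
    )


def device_contract_cost(monthly_fee: float, contract_years: float) -> float:
    """Total subscription cost over the contract term."""
    if monthly_fee < 0 or contract_years <= 0:
        raise ValueError("monthly fee must be >= 0 and contract years > 0")
    return monthly_fee * 12.0 * contract_years
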
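"""Optional rendering of the cost-effectiveness plane and the CEAC.

Matplotlib is imported lazily so the modelling core has no plotting
dependency; install the ``plot`` extra to use these helpers.
"""

from __future__ import annotations

from .sensitivity import PsaResult

__all__ = ["plot_ce_plane", "plot_ceac"]


def plot_ce_plane(result: PsaResult, path=None, ax=None):
    """Scatter of (ΔQALY, ΔCost) draws with the WTP threshold line."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    dq, dc = result.draws[:, 1], result.draws[:, 0]
    ax.scatter(dq, dc, s=6, alpha=0.4)
    lim = max(abs(dq).max(), 1e-6)
    ax.plot([-lim, lim], [-result.wtp * lim, result.wtp * lim],
            "k--", lw=0.8, label=f"WTP ${result.wtp:,.0f}/QALY")
    ax.axhline(0, color="grey", lw=0.5)
    ax.axvline(0, color="grey", lw=0.5)
    ax.set_xlabel("incremental QALYs")
    ax.set_ylabel("incremental cost (CAD)")
    ax.legend(loc="best", fontsize=8)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax


def plot_ceac(result: PsaResult, path=None, ax=None):
    """Cost-effectiveness acceptability curve over the WTP grid."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    pts = sorted(result.ceac.items())
    ax.plot([w for w, _ in pts], [a for _, a in pts], marker="o", ms=3)
    ax.set_xlabel("willingness-to-pay (CAD/QALY)")
    ax.set_ylabel("probability cost-effective")
    ax.set_ylim(0, 1)
    if path is not None:
        ax.figure.savefig(path, dpi=150, bbox_inches="tight")
    return ax
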
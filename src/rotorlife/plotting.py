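"""Static matplotlib figures: phasor plots and two-channel aggregation traces."""

from __future__ import annotations

import numpy as np

from .phasor import PhasorPoint
from .regions import ReferencePhasorSet
from .species import AggregationTrace

__all__ = ["plot_phasor", "plot_trace"]


def plot_phasor(
    trajectory: list[PhasorPoint],
    references: list[ReferencePhasorSet] | None = None,
    ax=None,
    show_circle: bool = True,
):
    """Phasor plot: trajectory points with 2-sigma error bars, optional
    reference sets, and the universal semicircle."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 4))
    if show_circle:
        theta = np.linspace(0, np.pi, 200)
        ax.plot(0.5 + 0.5 * np.cos(theta), 0.5 * np.sin(theta), "k-", lw=0.8, alpha=0.6)
    colors = {"fibril": "black", "stabilized_oligomer": "green"}
    for ref in references or []:
        g = [p.g for p in ref.points]
        s = [p.s for p in ref.points]
        ge = [p.g_err for p in ref.points]
        se = [p.s_err for p in ref.points]
        ax.errorbar(g, s, xerr=ge, yerr=se, fmt="s", ms=3, lw=0.8,
                    color=colors.get(ref.label, "gray"), label=ref.label)
    g = [p.g for p in trajectory]
    s = [p.s for p in trajectory]
    sc = ax.scatter(g, s, c=np.arange(len(g)), cmap="viridis", s=12, zorder=3,
                    label="aggregation")
    ax.figure.colorbar(sc, ax=ax, label="timepoint index")
    ax.set_xlabel("g")
    ax.set_ylabel("s")
    ax.legend(fontsize=8)
    return ax


def plot_trace(trace: AggregationTrace, ax=None):
    """Intensity (left axis) and tau_m (right axis) against aggregation time."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ax.plot(trace.time_h, trace.intensity, "o-", ms=3, mfc="none", color="tab:blue",
            label="intensity")
    ax.set_xlabel("time (h)")
    ax.set_ylabel("intensity (a.u.)", color="tab:blue")
    ax2 = ax.twinx()
    tau = trace.tau_m if trace.tau_m is not None else trace.tau_m_model
    ax2.plot(trace.time_h, tau, "o-", ms=3, color="tab:orange", label=r"$\tau_m$")
    ax2.set_ylabel(r"$\tau_m$ (ns)", color="tab:orange")
    return ax
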
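"""Small matplotlib helpers for trajectories and timepoint tables."""

from __future__ import annotations

from .observables import population_average
from .params import REGIONS


def plot_trajectory(traj, quantities=(("K36", "nucleation"), ("K36", "body"),
                                      ("K27", "nucleation"), ("K27", "body"),
                                      ("mRNA", "NA")), axes=None):
    """One panel per observable over the full schedule; returns the axes."""
    import matplotlib.pyplot as plt

    n = len(quantities)
    if axes is None:
        _, axes = plt.subplots(n, 1, figsize=(7, 1.8 * n), sharex=True)
    if n == 1:
        axes = [axes]
    for ax, (q, reg) in zip(axes, quantities):
        series = population_average(traj, q, reg)
        ax.plot(series.times, series.values)
        ax.set_ylabel(f"{q}" + (f"\n{reg}" if reg in REGIONS else ""))
        sched = traj.schedule
        if sched.cold_phase_index is not None:
            ax.axvspan(sched.cold_start, sched.cold_end, alpha=0.15,
                       color="tab:blue", lw=0)
    axes[-1].set_xlabel("time (days)")
    return axes


def plot_timepoint_bars(table, ax=None):
    """Bar chart of an observable_table slice (one quantity/region)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3))
    ax.bar(table["timepoint"], table["value"])
    ax.set_ylabel("model observable")
    return ax
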
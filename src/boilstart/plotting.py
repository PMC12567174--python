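"""Minimal control-chart plotting."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt

from .mspc import MonitorRecord

__all__ = ["plot_control_chart"]


def plot_control_chart(records: list[MonitorRecord], statistic: str = "t2",
                       ax=None, onset_time_min: float | None = None):
    """Plot a statistic trail against its control limit over time.

    ``statistic`` is ``"t2"`` or ``"spe"``; an optional vertical line marks
    the true onset.  Returns the matplotlib axes.
    """
    if statistic not in ("t2", "spe"):
        raise ValueError("statistic must be 't2' or 'spe'")
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 3.5))
    t = [r.time_min for r in records]
    val = [getattr(r, statistic) for r in records]
    lim = [getattr(r, f"{statistic}_limit") for r in records]
    label = "Hotelling's $T^2$" if statistic == "t2" else "SPE"
    ax.plot(t, val, "o-", ms=3, label=label)
    ax.plot(t, lim, "r--", label="control limit")
    if onset_time_min is not None:
        ax.axvline(onset_time_min, color="b", alpha=0.5, label="true onset")
    ax.set_xlabel("time (min)")
    ax.set_ylabel(label)
    ax.set_yscale("log")
    ax.legend(fontsize=8)
    return ax
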
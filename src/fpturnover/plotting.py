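"""Convenience plots (non-contract): time courses and decay fits."""

from __future__ import annotations

import numpy as np

from .kinetics import DecayFit
from .timecourse import GroupTimecourse


def plot_timecourse(tc: GroupTimecourse, ax=None):
    """Group mean fluorescence vs day with SD error bars."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    ax.errorbar(tc.days, tc.group_mean, yerr=tc.group_sd, marker="o",
                capsize=3, label=tc.group)
    ax.set_xlabel("day")
    ax.set_ylabel("fluorescence (AU)")
    ax.legend()
    return ax


def plot_decay_fit(times, values, fit: DecayFit, ax=None):
    """ln(fluorescence) points with the fitted decay line over the window."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    pos = values > 0
    ax.plot(times[pos], np.log(values[pos]), "o")
    lo, hi = fit.window
    tt = np.linspace(times[lo], times[hi], 50)
    label = (
        f"slope {fit.slope:.4f}, t½ "
        + (f"{fit.half_life:.2f} {fit.time_unit}" if fit.half_life_defined else "n/a")
    )
    ax.plot(tt, fit.intercept + fit.slope * tt, "-", label=label)
    ax.set_xlabel(f"time ({fit.time_unit})")
    ax.set_ylabel("ln fluorescence")
    ax.legend()
    return ax
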
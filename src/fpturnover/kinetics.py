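"""Half-life estimation from fluorescence decay, plus AUC.

After a pulse of conditional expression ends, fluorescent-protein signal
decays by first-order kinetics: F(t) = F_peak * exp(b * (t - t_peak)) with
b < 0, so ln F is linear in t and the half-life is t1/2 = ln 2 / |b|. The
decay window runs from the global fluorescence peak to the subsequent global
minimum; an ordinary least-squares fit of ln(fluorescence) on time over that
window gives the slope b, its standard error, and r².

The same machinery serves daily in vivo video data (time unit: days),
per-fly microscope time courses (days) and plate-reader kinetics (minutes);
the time unit is carried explicitly and never converted silently.

``DecayModel`` / ``DecayFit`` follow the model/results split: the model holds
the data, ``fit()`` returns a results object with estimates, uncertainties
and a ``summary()`` table.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .errors import DataError, NoDecayWindowError
from .timecourse import GroupTimecourse

__all__ = [
    "DecayModel",
    "DecayFit",
    "AUCResult",
    "find_decay_window",
    "fit_decay",
    "half_life_from_slope",
    "compute_auc",
    "auc_fold_change",
    "windowed_ln_points",
]

LN2 = math.log(2.0)
logger = logging.getLogger(__name__)


def find_decay_window(values) -> tuple[int, int]:
    """Peak-to-minimum window indices of a fluorescence time course.

    The peak is the global maximum (earliest index on ties); the minimum is
    the global minimum among points strictly after the peak (earliest on
    ties). Intermediate bumps between the two are retained — the window is a
    contiguous index range, not a monotone subsequence.
    """
    if isinstance(values, GroupTimecourse):
        values = values.group_mean.to_numpy()
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 3:
        raise DataError(f"need >= 3 time points to locate a decay window, got {values.shape}")
    peak = int(np.argmax(values))
    if peak == len(values) - 1:
        raise NoDecayWindowError(
            "fluorescence peaks at the last time point: no decay window exists"
        )
    minimum = peak + 1 + int(np.argmin(values[peak + 1 :]))
    return peak, minimum


@dataclass(frozen=True)
class DecayFit:
    """OLS results for ln(fluorescence) vs time over a decay window.

    ``half_life`` is ln 2 / |slope| in the model's time unit when the slope
    is negative; for a non-decaying fit (slope >= 0) it is NaN and
    ``half_life_defined`` is False — never a fabricated large number.
    """

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n_points: int
    window: tuple[int, int]
    time_unit: str = "days"

    @property
    def half_life(self) -> float:
        if not self.half_life_defined:
            return float("nan")
        return LN2 / abs(self.slope)

    @property
    def half_life_defined(self) -> bool:
        return self.slope < 0

    def summary(self) -> str:
        lines = [
            "Exponential decay fit (OLS on ln fluorescence)",
            "-" * 46,
            f"slope        {self.slope: .6g} per {self.time_unit.rstrip('s')}",
            f"slope SE     {self.slope_se: .6g}",
            f"half-life    "
            + (
                f"{self.half_life:.2f} {self.time_unit}"
                if self.half_life_defined
                else "undefined (non-negative slope)"
            ),
            f"r-squared    {self.r_squared: .4f}",
            f"n points     {self.n_points}",
            f"window       {self.window[0]}..{self.window[1]} (inclusive)",
        ]
        return "\n".join(lines)


class DecayModel:
    """Log-linear exponential decay model for one fluorescence time course.

    Parameters
    ----------
    times, values
        Time points and non-log fluorescence values (arbitrary units).
    time_unit
        "days" for in vivo/microscope data, "minutes" for plate-reader data.
    """

    def __init__(self, times, values, time_unit: str = "days") -> None:
        self.times = np.asarray(times, dtype=float)
        self.values = np.asarray(values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise DataError("times and values must be 1-D arrays of equal length")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise DataError("time points must be strictly increasing")
        self.time_unit = time_unit

    @classmethod
    def from_timecourse(cls, tc: GroupTimecourse, time_unit: str = "days") -> "DecayModel":
        """Build a model from a group time course's per-day group means."""
        return cls(tc.days, tc.group_mean.to_numpy(), time_unit=time_unit)

    def find_window(self) -> tuple[int, int]:
        return find_decay_window(self.values)

    def fit(self, window: tuple[int, int] | None = None) -> DecayFit:
        """OLS of ln(value) on time over the (peak, minimum) window.

        Nonpositive values inside the window cannot be log-transformed; they
        are dropped with a logged warning rather than offset (an epsilon
        offset would bias the slope). At least two usable points are
        required; the slope standard error is defined from three points up.
        """
        if window is None:
            window = self.find_window()
        lo, hi = window
        if not (0 <= lo < hi < len(self.times)):
            raise DataError(f"window {window} out of bounds for {len(self.times)} points")
        t = self.times[lo : hi + 1]
        v = self.values[lo : hi + 1]
        usable = v > 0
        if not usable.all():
            logger.warning(
                "fit_decay: dropping %d nonpositive fluorescence value(s) before ln",
                int((~usable).sum()),
            )
        t, v = t[usable], v[usable]
        if len(t) < 2:
            raise DataError(
                f"fewer than 2 positive values in window {window}: cannot fit"
            )
        res = sps.linregress(t, np.log(v))
        slope = float(res.slope)
        if slope >= 0:
            logger.warning("fit_decay: non-negative slope %g — half-life undefined", slope)
        return DecayFit(
            slope=slope,
            intercept=float(res.intercept),
            slope_se=float(res.stderr) if len(t) >= 3 else float("nan"),
            r_squared=float(res.rvalue) ** 2,
            n_points=int(len(t)),
            window=(lo, hi),
            time_unit=self.time_unit,
        )


def fit_decay(times, values, window=None, time_unit: str = "days") -> DecayFit:
    """Functional shortcut for ``DecayModel(times, values).fit(window)``."""
    return DecayModel(times, values, time_unit=time_unit).fit(window)


def half_life_from_slope(slope: float) -> float:
    """Half-life ln 2 / |slope| for a negative decay slope.

    The result is in the reciprocal of the slope's time unit (slope per day
    -> half-life in days).
    """
    if not slope < 0:
        raise DataError(f"half-life requires a negative decay slope, got {slope}")
    return LN2 / abs(slope)


@dataclass(frozen=True)
class AUCResult:
    """Area under the fluorescence-time curve: total protein accumulation."""

    auc: float
    span: tuple[float, float]
    method: str = "trapezoid"


def compute_auc(times, values=None) -> AUCResult:
    """Trapezoidal AUC of a fluorescence time course over its full span."""
    if isinstance(times, GroupTimecourse):
        tc = times
        times, values = tc.days, tc.group_mean.to_numpy()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(times) < 2:
        raise DataError("AUC requires at least 2 time points")
    if np.any(np.diff(times) <= 0):
        raise DataError("time points must be strictly increasing for AUC")
    auc = float(np.trapezoid(values, times))
    return AUCResult(auc=auc, span=(float(times[0]), float(times[-1])))


def auc_fold_change(treated: AUCResult, control: AUCResult) -> float:
    """Ratio of treated to control AUC (e.g. drug-induced accumulation)."""
    if control.auc <= 0:
        raise DataError(f"control AUC must be > 0, got {control.auc}")
    return treated.auc / control.auc


def windowed_ln_points(
    times, values=None, window=None
) -> tuple[np.ndarray, np.ndarray]:
    """The (time, ln fluorescence) points a decay fit would use.

    Shares window selection and nonpositive-value handling with
    ``DecayModel.fit`` so that slope-comparison tests operate on exactly the
    points behind the reported slopes.
    """
    if isinstance(times, GroupTimecourse):
        tc = times
        times, values = tc.days, tc.group_mean.to_numpy()
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    if window is None:
        window = find_decay_window(values)
    lo, hi = window
    t = times[lo : hi + 1]
    v = values[lo : hi + 1]
    usable = v > 0
    return t[usable], np.log(v[usable])
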
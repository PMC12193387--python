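"""Synthetic turnover experiments with known ground truth.

Generates everything the wet lab would: video frame stacks of flies moving
inside a vial (two camera views per vial, several vials per group, one
recording per day), plate-reader decay series sampled every 30 s, and tables
of half-life values stratified by age and sex. Every output comes with its
generating parameters, so downstream quantification, aggregation, fitting
and statistics can be tested against exact ground truth.

Forward model for the video assay
---------------------------------
Each fly is a hard disk of uniform intensity performing a Gaussian-step
random walk reflected at the vial ROI boundary. Per-fly intensity on day d
follows the induction-pulse shape: a linear rise to the peak day, then
first-order decay, I_d = I_peak * 2**(-(d - peak_day)/t_half) for
d >= peak_day. Fly pixels carry the summed intensity of the flies covering
them (flies occlude the background), all other pixels sit at the background
level, and per-pixel additive Gaussian noise (clipped at zero, as detector
counts are non-negative) is applied last. The two cameras are independent
position realizations of the same vial — the pipeline only sums intensities,
so no geometric stereo model is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .quantify import FrameStack

__all__ = [
    "SimConfig",
    "GroundTruth",
    "simulate_video_experiment",
    "simulate_plate_series",
    "simulate_daily_decay",
    "simulate_halflife_table",
]

LN2 = math.log(2.0)


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated video experiment.

    Defaults mirror the assay design: 6 flies per vial, 4 vials per group,
    daily recordings over 6 days, fluorescence peaking one day after the end
    of induction and decaying with a 3.5-day half-life (tissue-general eGFP
    in control flies), two synchronized cameras recording at 30 fps.
    Intensities are arbitrary fluorescence units (AU).
    """

    n_flies: int = 6
    fly_radius_px: int = 2
    fly_peak_intensity: float = 1000.0
    background_level: float = 50.0
    noise_sd: float = 10.0
    frame_shape: tuple[int, int] = (64, 64)
    n_frames_per_day: int = 30
    fps: float = 30.0
    n_days: int = 6
    true_half_life: float = 3.5
    peak_day: int = 1
    n_vials: int = 4
    n_cameras: int = 2
    step_sd_px: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.fly_peak_intensity > self.background_level >= 0):
            raise ConfigurationError(
                "need fly_peak_intensity > background_level >= 0, got "
                f"{self.fly_peak_intensity} and {self.background_level}"
            )
        if self.noise_sd < 0:
            raise ConfigurationError(f"noise_sd must be >= 0, got {self.noise_sd}")
        if self.true_half_life <= 0:
            raise ConfigurationError(
                f"true_half_life must be > 0, got {self.true_half_life}"
            )
        for name in ("n_flies", "fly_radius_px", "n_frames_per_day", "n_days",
                     "n_vials", "n_cameras"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be >= 1")
        if not (0 <= self.peak_day < self.n_days):
            raise ConfigurationError(
                f"peak_day {self.peak_day} outside 0..{self.n_days - 1}"
            )
        h, w = self.frame_shape
        d = 2 * self.fly_radius_px + 1
        roi_h, roi_w = h - 2 * self.fly_radius_px, w - 2 * self.fly_radius_px
        if (roi_h // d) * (roi_w // d) < self.n_flies:
            raise ConfigurationError(
                f"frame {self.frame_shape} too small to contain {self.n_flies} "
                f"non-overlapping flies of radius {self.fly_radius_px} px "
                "inside the vial ROI"
            )

    @property
    def true_slope(self) -> float:
        """Decay slope of ln(fluorescence) per day: -ln 2 / half-life."""
        return -LN2 / self.true_half_life

    @property
    def disk_area_px(self) -> int:
        r = self.fly_radius_px
        yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
        return int((yy**2 + xx**2 <= r**2).sum())

    def day_intensity(self, day: int) -> float:
        """Per-fly pixel intensity on a given day (induction rise then decay)."""
        if day >= self.peak_day:
            return self.fly_peak_intensity * 2.0 ** (
                -(day - self.peak_day) / self.true_half_life
            )
        return self.fly_peak_intensity * (day + 1) / (self.peak_day + 1)


@dataclass
class GroundTruth:
    """Exact generating quantities of a simulated video experiment.

    ``per_day_vial`` has one row per (day, vial) with the true total fly
    fluorescence visible to either camera (noise-free); after the peak day it
    decays exactly exponentially. ``trajectories`` maps
    (day, vial, camera) -> array (n_frames, n_flies, 2) of fly centres.
    """

    per_day_vial: pd.DataFrame
    true_slope: float
    true_half_life: float
    peak_day: int
    trajectories: dict = field(default_factory=dict, repr=False)

    def true_total(self, day: int, vial: int) -> float:
        df = self.per_day_vial
        row = df[(df["day"] == day) & (df["vial"] == vial)]
        return float(row["true_total"].iloc[0])


def _disk_offsets(radius: int) -> tuple[np.ndarray, np.ndarray]:
    yy, xx = np.mgrid[-radius : radius + 1, -radius : radius + 1]
    inside = yy**2 + xx**2 <= radius**2
    return yy[inside], xx[inside]


def _initial_positions(rng, n_flies, lo, hi_r, hi_c, radius):
    """Rejection-sample non-overlapping fly centres; fall back to a grid."""
    min_dist = 2 * radius + 1
    for _ in range(200):
        pos = np.column_stack(
            [rng.uniform(lo, hi_r, size=n_flies), rng.uniform(lo, hi_c, size=n_flies)]
        )
        d = np.linalg.norm(pos[:, None, :] - pos[None, :, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() > min_dist:
            return pos
    # dense case: regular grid jittered within half a cell
    cells_r = int((hi_r - lo) // min_dist) + 1
    grid = []
    for i in range(n_flies):
        grid.append([lo + (i % cells_r) * min_dist, lo + (i // cells_r) * min_dist])
    return np.asarray(grid, dtype=float)


def _reflect(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    # reflect positions into [lo, hi] (handles multiple bounces)
    span = hi - lo
    y = np.mod(x - lo, 2 * span)
    y = np.where(y > span, 2 * span - y, y)
    return y + lo


def simulate_video_experiment(
    config: SimConfig,
) -> tuple[dict, GroundTruth]:
    """Simulate a full multi-day, multi-vial, two-camera video experiment.

    Returns ``(stacks, truth)`` where ``stacks`` maps
    ``(day, vial, camera)`` -> :class:`~fpturnover.quantify.FrameStack` and
    ``truth`` records the exact generating quantities. Identical config and
    seed give bit-identical output.
    """
    rng = np.random.default_rng(config.seed)
    h, w = config.frame_shape
    r = config.fly_radius_px
    lo = float(r)
    hi_r, hi_c = float(h - 1 - r), float(w - 1 - r)
    dy, dx = _disk_offsets(r)
    area = config.disk_area_px

    stacks: dict[tuple[int, int, int], FrameStack] = {}
    trajectories: dict[tuple[int, int, int], np.ndarray] = {}
    rows = []
    for day in range(config.n_days):
        intensity = config.day_intensity(day)
        for vial in range(config.n_vials):
            rows.append(
                {
                    "day": day,
                    "vial": vial,
                    "true_intensity": intensity,
                    "true_total": intensity * area * config.n_flies,
                }
            )
            for cam in range(config.n_cameras):
                pos = _initial_positions(rng, config.n_flies, lo, hi_r, hi_c, r)
                traj = np.empty((config.n_frames_per_day, config.n_flies, 2))
                frames = []
                for f in range(config.n_frames_per_day):
                    if f > 0:
                        pos = pos + rng.normal(
                            0.0, config.step_sd_px, size=pos.shape
                        )
                        pos[:, 0] = _reflect(pos[:, 0], lo, hi_r)
                        pos[:, 1] = _reflect(pos[:, 1], lo, hi_c)
                    traj[f] = pos
                    frame = np.zeros((h, w), dtype=float)
                    centers = np.rint(pos).astype(int)
                    for cy, cx in centers:
                        frame[cy + dy, cx + dx] += intensity
                    frame[frame == 0] = config.background_level
                    if config.noise_sd > 0:
                        frame += rng.normal(0.0, config.noise_sd, size=frame.shape)
                        np.clip(frame, 0.0, None, out=frame)
                    frames.append(frame)
                key = (day, vial, cam)
                stacks[key] = FrameStack(
                    frames=frames,
                    fps=config.fps,
                    camera_id=f"cam{cam}",
                    vial_id=f"vial{vial}",
                    day=float(day),
                )
                trajectories[key] = traj

    truth = GroundTruth(
        per_day_vial=pd.DataFrame(rows),
        true_slope=config.true_slope,
        true_half_life=config.true_half_life,
        peak_day=config.peak_day,
        trajectories=trajectories,
    )
    return stacks, truth


def simulate_plate_series(
    true_half_life_min: float,
    duration_min: float,
    interval_s: float = 30.0,
    noise_cv: float = 0.0,
    initial_fluorescence: float = 1000.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Plate-reader fluorescence decay sampled at fixed intervals.

    Readings follow F(t) = F0 * 2**(-t / t_half) with multiplicative
    lognormal noise of coefficient of variation ``noise_cv`` (mean 1, so the
    expected reading is unbiased). Timestamps are in minutes. Returns a
    DataFrame with columns ``time_min`` and ``fluorescence``.
    """
    if true_half_life_min <= 0:
        raise ConfigurationError(
            f"true_half_life_min must be > 0, got {true_half_life_min}"
        )
    t = np.arange(0.0, duration_min + 1e-9, interval_s / 60.0)
    f = initial_fluorescence * 2.0 ** (-t / true_half_life_min)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        f = f * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.shape)
    return pd.DataFrame({"time_min": t, "fluorescence": f})


def simulate_daily_decay(
    true_half_life_days: float,
    n_days: int = 6,
    noise_cv: float = 0.10,
    initial_fluorescence: float = 1000.0,
    seed: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Daily group-mean fluorescence during pure decay (no induction rise).

    A lightweight stand-in for the aggregated output of a video experiment
    once the peak has passed: F(d) = F0 * 2**(-d / t_half) with
    multiplicative lognormal noise of coefficient of variation ``noise_cv``
    (mean 1). Returns ``(days, values)``; used for slope-comparison power and
    calibration studies where rendering frames would add nothing.
    """
    if true_half_life_days <= 0:
        raise ConfigurationError(
            f"true_half_life_days must be > 0, got {true_half_life_days}"
        )
    if n_days < 2:
        raise ConfigurationError(f"n_days must be >= 2, got {n_days}")
    t = np.arange(n_days, dtype=float)
    f = initial_fluorescence * 2.0 ** (-t / true_half_life_days)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = math.sqrt(math.log1p(noise_cv**2))
        f = f * rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=t.shape)
    return t, f


def simulate_halflife_table(
    n_per_cell: int,
    effects: Mapping[str, float] | None = None,
    residual_sd: float = 0.5,
    baseline: float = 4.0,
    seed: int | None = None,
) -> pd.DataFrame:
    """Balanced table of half-life values from a two-factor linear model.

    half_life = baseline + age*[old] + sex*[female] + interaction*[old,female]
    + N(0, residual_sd), with ``n_per_cell`` rows in each of the four
    (age_group, sex) cells. ``effects`` keys: ``age``, ``sex``,
    ``interaction`` (days; missing keys default to 0). The baseline of 4 days
    is a typical tissue-general eGFP half-life.
    """
    if n_per_cell < 2:
        raise ConfigurationError(f"n_per_cell must be >= 2, got {n_per_cell}")
    eff = {"age": 0.0, "sex": 0.0, "interaction": 0.0}
    if effects:
        unknown = set(effects) - set(eff)
        if unknown:
            raise ConfigurationError(f"unknown effect names: {sorted(unknown)}")
        eff.update(effects)
    rng = np.random.default_rng(seed)
    rows = []
    for age in ("young", "old"):
        for sex in ("male", "female"):
            mean = (
                baseline
                + eff["age"] * (age == "old")
                + eff["sex"] * (sex == "female")
                + eff["interaction"] * (age == "old" and sex == "female")
            )
            values = mean + rng.normal(0.0, residual_sd, size=n_per_cell)
            for i, v in enumerate(values):
                rows.append(
                    {
                        "half_life": v,
                        "age_group": age,
                        "sex": sex,
                        "experiment_id": f"{age}-{sex}-{i}",
                    }
                )
    return pd.DataFrame(rows)
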
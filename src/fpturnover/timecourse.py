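"""Camera merging, sub-threshold filtering and daily/group aggregation.

The two synchronized cameras view the same vial from different angles; their
per-frame totals are summed to one merged stream, frames whose merged total
falls at or below the signal threshold are dropped, the surviving frames of a
recording are averaged into one fluorescence value per vial per day, and
vials are averaged into a group time course (mean and sample SD across
vials).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError, SynchronizationError
from .quantify import FrameFluorescence

__all__ = [
    "FluorescenceSeries",
    "GroupTimecourse",
    "merge_cameras",
    "vial_day_value",
    "aggregate_group",
]

logger = logging.getLogger(__name__)


@dataclass
class FluorescenceSeries:
    """Per-frame total fluorescence for one camera (or a merged pair)."""

    records: Sequence[FrameFluorescence]
    camera_ids: tuple[str, ...] = ("cam0",)
    vial_id: str = "vial0"
    day: float = 0.0

    def __post_init__(self) -> None:
        self.records = list(self.records)
        if not self.records:
            raise DataError("a FluorescenceSeries must contain at least one record")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def totals(self) -> np.ndarray:
        return np.array([r.total_fluorescence for r in self.records], dtype=float)

    @property
    def frame_indices(self) -> np.ndarray:
        return np.array([r.frame_index for r in self.records], dtype=int)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_indices,
                "camera_id": "+".join(self.camera_ids),
                "vial_id": self.vial_id,
                "day": self.day,
                "total_fluorescence": self.totals,
                "n_objects": [r.n_objects for r in self.records],
            }
        )


def merge_cameras(
    series_a: FluorescenceSeries,
    series_b: FluorescenceSeries,
    signal_threshold: float = 0.0,
) -> FluorescenceSeries:
    """Sum two synchronized camera streams frame-by-frame and filter.

    The merged per-frame total is the sum of the two per-frame totals; frames
    whose merged total is <= ``signal_threshold`` are removed (they carry no
    usable fly signal, e.g. all flies momentarily out of both views). Order
    is preserved.
    """
    if len(series_a) != len(series_b):
        raise SynchronizationError(
            f"camera streams differ in length: {len(series_a)} vs {len(series_b)}"
        )
    if not np.array_equal(series_a.frame_indices, series_b.frame_indices):
        raise SynchronizationError("camera streams have mismatched frame indices")
    if series_a.vial_id != series_b.vial_id or series_a.day != series_b.day:
        raise SynchronizationError(
            "camera streams belong to different vials or days: "
            f"({series_a.vial_id}, {series_a.day}) vs ({series_b.vial_id}, {series_b.day})"
        )

    merged = []
    n_dropped = 0
    for ra, rb in zip(series_a.records, series_b.records):
        total = ra.total_fluorescence + rb.total_fluorescence
        if total <= signal_threshold:
            n_dropped += 1
            continue
        merged.append(
            FrameFluorescence(ra.frame_index, total, ra.n_objects + rb.n_objects)
        )
    if n_dropped:
        logger.warning(
            "merge_cameras: dropped %d/%d frames at or below signal threshold %g "
            "(vial %s, day %g)",
            n_dropped, len(series_a), signal_threshold, series_a.vial_id, series_a.day,
        )
    if not merged:
        raise DataError(
            f"all {len(series_a)} frames fell at or below the signal threshold "
            f"{signal_threshold} (vial {series_a.vial_id}, day {series_a.day})"
        )
    return FluorescenceSeries(
        records=merged,
        camera_ids=series_a.camera_ids + series_b.camera_ids,
        vial_id=series_a.vial_id,
        day=series_a.day,
    )


def vial_day_value(merged: FluorescenceSeries) -> float:
    """Arithmetic mean of the surviving per-frame totals: one value per vial per day."""
    return float(np.mean(merged.totals))


@dataclass
class GroupTimecourse:
    """Per-day fluorescence for one group: per-vial means plus group mean/SD.

    ``vial_means`` is indexed by day with one column per vial; ``group_mean``
    is the arithmetic mean across vials per day and ``group_sd`` the sample
    standard deviation (n-1 denominator), NaN where fewer than two vials
    reported a value.
    """

    group: str
    vial_means: pd.DataFrame
    group_mean: pd.Series = field(init=False)
    group_sd: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        days = self.vial_means.index.to_numpy(dtype=float)
        if len(days) and np.any(np.diff(days) <= 0):
            raise DataError("days must be strictly increasing")
        self.group_mean = self.vial_means.mean(axis=1)
        counts = self.vial_means.notna().sum(axis=1)
        sd = self.vial_means.std(axis=1, ddof=1)
        sd[counts < 2] = np.nan
        self.group_sd = sd

    @property
    def days(self) -> np.ndarray:
        return self.vial_means.index.to_numpy(dtype=float)

    @property
    def n_vials(self) -> int:
        return self.vial_means.shape[1]

    def to_csv(self, path) -> None:
        df = self.vial_means.copy()
        df.insert(0, "group", self.group)
        df["group_mean"] = self.group_mean
        df["group_sd"] = self.group_sd
        df.index.name = "day"
        df.to_csv(path)

    @classmethod
    def from_csv(cls, path) -> "GroupTimecourse":
        df = pd.read_csv(path, index_col="day")
        groups = df["group"].unique()
        if len(groups) != 1:
            raise DataError(f"summary file contains {len(groups)} groups, expected 1")
        vials = df.drop(columns=["group", "group_mean", "group_sd"])
        return cls(group=str(groups[0]), vial_means=vials)


def aggregate_group(
    vial_values: Mapping[str, Mapping[float, float]], group: str
) -> GroupTimecourse:
    """Combine per-vial daily values into one group time course.

    ``vial_values`` maps vial id -> {day: mean fluorescence}. Vials must share
    one day grid; missing values (NaN, or a day absent from a vial) are
    allowed and flagged but excluded from the group mean/SD for that day.
    """
    if not vial_values:
        raise DataError("aggregate_group requires at least one vial")
    frame = pd.DataFrame(
        {vial: pd.Series(dict(vals), dtype=float) for vial, vals in vial_values.items()}
    ).sort_index()
    n_missing = int(frame.isna().sum().sum())
    if n_missing:
        logger.warning(
            "aggregate_group(%s): %d missing vial-day values excluded", group, n_missing
        )
    return GroupTimecourse(group=group, vial_means=frame)
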
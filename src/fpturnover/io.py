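"""File formats: 16-bit grayscale image sequences with a manifest, masks,
per-frame fluorescence CSVs and fit/stats report CSVs.

Frames are stored as one image file per frame (PNG by default) rather than
as video: image sequences are bit-exact and codec-free, so a rerun of the
pipeline on the same inputs is byte-identical. A manifest CSV ties the files
together with columns ``frame_index, camera_id, vial_id, day, filename``.
"""

from __future__ import annotations

import os
from pathlib import Path
from typing import Iterable

import imageio.v3 as iio
import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .quantify import FrameStack
from .timecourse import FluorescenceSeries
from .quantify import FrameFluorescence

MANIFEST_COLUMNS = ["frame_index", "camera_id", "vial_id", "day", "filename"]
PER_FRAME_COLUMNS = [
    "frame_index", "camera_id", "vial_id", "day", "total_fluorescence", "n_objects",
]


def write_experiment(stacks: dict, truth, out_dir, fmt: str = "png") -> Path:
    """Write simulated stacks as 16-bit grayscale image sequences.

    Layout: ``<out_dir>/day<d>/vial<v>/cam<c>/frame<i>.png`` plus
    ``manifest.csv`` and ``ground_truth.csv`` at the top level. Intensities
    are rounded to the nearest integer and stored as uint16; callers should
    keep simulated intensities below 65535.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for (day, vial, cam), stack in sorted(stacks.items()):
        sub = out_dir / f"day{day}" / f"vial{vial}" / f"cam{cam}"
        sub.mkdir(parents=True, exist_ok=True)
        for i, frame in enumerate(stack.frames):
            if frame.max() > 65535:
                raise DataError(
                    f"frame intensity {frame.max():.0f} exceeds the uint16 range"
                )
            fname = sub / f"frame{i:05d}.{fmt}"
            iio.imwrite(fname, np.rint(frame).astype(np.uint16))
            rows.append(
                {
                    "frame_index": i,
                    "camera_id": stack.camera_id,
                    "vial_id": stack.vial_id,
                    "day": stack.day,
                    "filename": str(fname.relative_to(out_dir)),
                }
            )
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(
        out_dir / "manifest.csv", index=False
    )
    truth.per_day_vial.to_csv(out_dir / "ground_truth.csv", index=False)
    return out_dir


def read_manifest(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"manifest not found: {path}")
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"manifest is missing columns: {sorted(missing)}")
    return df


def read_stack(manifest: pd.DataFrame, root, camera_id: str, vial_id: str,
               day: float, fps: float = 30.0) -> FrameStack:
    """Load one (camera, vial, day) frame stack listed in a manifest."""
    root = Path(root)
    sel = manifest[
        (manifest["camera_id"] == camera_id)
        & (manifest["vial_id"] == vial_id)
        & (manifest["day"] == day)
    ].sort_values("frame_index")
    if sel.empty:
        raise DataError(
            f"manifest has no frames for camera={camera_id}, vial={vial_id}, day={day}"
        )
    frames = [
        np.asarray(iio.imread(root / fname), dtype=float)
        for fname in sel["filename"]
    ]
    return FrameStack(frames=frames, fps=fps, camera_id=camera_id,
                      vial_id=vial_id, day=float(day))


def read_mask(path) -> np.ndarray:
    """Binary exclusion mask from an image file; nonzero pixels are excluded."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"mask file not found: {path}")
    return np.asarray(iio.imread(path))


def write_per_frame_csv(series_list: Iterable[FluorescenceSeries], path) -> None:
    df = pd.concat([s.to_frame() for s in series_list], ignore_index=True)
    df.to_csv(path, index=False, columns=PER_FRAME_COLUMNS)


def read_per_frame_csv(path) -> list[FluorescenceSeries]:
    """Rebuild FluorescenceSeries objects (one per camera/vial/day) from CSV."""
    df = pd.read_csv(path)
    missing = set(PER_FRAME_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"per-frame CSV is missing columns: {sorted(missing)}")
    out = []
    for (cam, vial, day), grp in df.groupby(["camera_id", "vial_id", "day"], sort=True):
        grp = grp.sort_values("frame_index")
        records = [
            FrameFluorescence(int(r.frame_index), float(r.total_fluorescence),
                              int(r.n_objects))
            for r in grp.itertuples()
        ]
        out.append(
            FluorescenceSeries(
                records=records,
                camera_ids=tuple(str(cam).split("+")),
                vial_id=str(vial),
                day=float(day),
            )
        )
    return out
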
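"""Per-frame fly-fluorescence quantification.

A fly in a grayscale fluorescence video frame is a bright connected blob.
Quantification is deliberately simple and fully specified: within a
rectangular region of interest (ROI), excluding optionally masked pixels,
every pixel whose raw intensity strictly exceeds a detection threshold is a
candidate fly pixel; candidates are grouped into 8-connected components,
components smaller than ``min_blob_px`` are discarded, and the frame's total
fly fluorescence is the sum of raw intensities over the surviving pixels.

No background subtraction is performed: background is suppressed
experimentally (dark media, black filter paper), not computationally, and
summing raw intensities keeps the per-frame value proportional to the amount
of fluorescent protein in view.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np
from skimage import measure

from .errors import ConfigurationError, DataError

__all__ = [
    "QuantConfig",
    "FrameStack",
    "FrameFluorescence",
    "quantify_frame",
    "quantify_stack",
]


class FrameFluorescence(NamedTuple):
    """Quantification result for a single frame."""

    frame_index: int
    total_fluorescence: float
    n_objects: int


@dataclass(frozen=True)
class QuantConfig:
    """Detection parameters: threshold, ROI rectangle, optional exclusion mask.

    Parameters
    ----------
    threshold
        Pixel-level detection threshold (arbitrary fluorescence units).
        Comparison is strict: a pixel is a candidate iff intensity > threshold.
    roi
        ``(row_min, row_max, col_min, col_max)``, 0-based, half-open.
    mask
        Optional binary image with the same shape as the frames; nonzero
        pixels are excluded from quantification.
    min_blob_px
        Minimum connected-component size (8-connectivity) for a component to
        count as a fly. The default of 1 makes object filtering a no-op, so
        plain per-pixel thresholding semantics hold unless the user opts in.
    """

    threshold: float
    roi: tuple[int, int, int, int]
    mask: np.ndarray | None = field(default=None)
    min_blob_px: int = 1

    def __post_init__(self) -> None:
        if self.threshold < 0:
            raise ConfigurationError(f"threshold must be >= 0, got {self.threshold}")
        if self.min_blob_px < 1:
            raise ConfigurationError(f"min_blob_px must be >= 1, got {self.min_blob_px}")
        r0, r1, c0, c1 = self.roi
        if not (0 <= r0 < r1 and 0 <= c0 < c1):
            raise ConfigurationError(f"empty or inverted ROI: {self.roi}")
        if self.mask is not None:
            object.__setattr__(self, "mask", np.asarray(self.mask))

    def validate_shape(self, shape: tuple[int, int]) -> None:
        r0, r1, c0, c1 = self.roi
        if r1 > shape[0] or c1 > shape[1]:
            raise ConfigurationError(
                f"ROI {self.roi} exceeds frame bounds {shape}"
            )
        if self.mask is not None and self.mask.shape != tuple(shape):
            raise DataError(
                f"mask shape {self.mask.shape} does not match frame shape {shape}"
            )


@dataclass
class FrameStack:
    """Ordered single-channel frames from one camera at one time point.

    All frames share a single shape, intensities are non-negative and the
    nominal frame rate ``fps`` is positive.
    """

    frames: Sequence[np.ndarray]
    fps: float = 30.0
    camera_id: str = "cam0"
    vial_id: str = "vial0"
    day: float = 0.0

    def __post_init__(self) -> None:
        self.frames = [np.asarray(f) for f in self.frames]
        if self.fps <= 0:
            raise DataError(f"fps must be > 0, got {self.fps}")
        if self.frames:
            shape = self.frames[0].shape
            for i, f in enumerate(self.frames):
                if f.ndim != 2:
                    raise DataError(f"frame {i} is not 2-D (ndim={f.ndim})")
                if f.shape != shape:
                    raise DataError(
                        f"frame {i} shape {f.shape} differs from {shape}"
                    )
                if np.any(f < 0):
                    raise DataError(f"frame {i} contains negative intensities")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        if not self.frames:
            raise DataError("empty frame stack has no shape")
        return self.frames[0].shape


def quantify_frame(
    frame: np.ndarray, config: QuantConfig, frame_index: int = 0
) -> FrameFluorescence:
    """Total fly fluorescence and object count for one frame.

    Candidate pixels are those inside the ROI, not excluded by the mask, with
    intensity strictly above the threshold. 8-connected components of
    candidates with at least ``min_blob_px`` pixels are the detected objects;
    the total is the sum of raw intensities over object pixels.
    """
    frame = np.asarray(frame)
    if frame.ndim != 2:
        raise DataError(f"expected 2-D frame, got ndim={frame.ndim}")
    config.validate_shape(frame.shape)

    r0, r1, c0, c1 = config.roi
    candidate = np.zeros(frame.shape, dtype=bool)
    candidate[r0:r1, c0:c1] = frame[r0:r1, c0:c1] > config.threshold
    if config.mask is not None:
        candidate &= config.mask == 0

    if not candidate.any():
        return FrameFluorescence(frame_index, 0.0, 0)

    # 8-connectivity
    labels, n_components = measure.label(
        candidate, connectivity=2, return_num=True
    )
    if config.min_blob_px > 1:
        sizes = np.bincount(labels.ravel())
        keep = sizes >= config.min_blob_px
        keep[0] = False
        object_pixels = keep[labels]
        n_objects = int(keep.sum())
    else:
        object_pixels = candidate
        n_objects = int(n_components)

    total = float(frame[object_pixels].sum())
    return FrameFluorescence(frame_index, total, n_objects)


def quantify_stack(stack: FrameStack, config: QuantConfig) -> "FluorescenceSeries":
    """Quantify every frame of a stack, preserving frame order."""
    from .timecourse import FluorescenceSeries  # local import avoids a cycle

    if len(stack) == 0:
        raise DataError("cannot quantify an empty frame stack")
    records = []
    for i, frame in enumerate(stack.frames):
        try:
            records.append(quantify_frame(frame, config, frame_index=i))
        except (DataError, ConfigurationError) as exc:
            raise type(exc)(f"frame {i}: {exc}") from exc
    return FluorescenceSeries(
        records=records,
        camera_ids=(stack.camera_id,),
        vial_id=stack.vial_id,
        day=stack.day,
    )
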
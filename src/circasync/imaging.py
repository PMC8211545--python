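"""Raw bioluminescence image processing.

The chain mirrors intensified-CCD acquisition of luciferase reporter
signal from cultured whole brains: cosmic-ray frame rejection at
acquisition time, averaging into 45-min bins, pairwise running-minimum
denoising (removes single-frame transients such as hot pixels), and ROI
extraction with per-frame background subtraction.  Background varies per
frame, so extracted values may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .traces import CellTrace

__all__ = [
    "FrameStack",
    "ROI",
    "ROISet",
    "filter_cosmic_rays",
    "bin_frames",
    "running_minimum",
    "extract_traces",
    "to_photons_per_minute",
    "read_stack",
    "write_stack",
]


@dataclass
class FrameStack:
    """Ordered 2-D intensity frames with timestamps in hours."""

    frames: np.ndarray          # (n, h, w)
    timestamps: np.ndarray      # hours, strictly increasing
    exposure_min: float = 15.0
    missing: Optional[np.ndarray] = None  # True for empty (gap) bins

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        self.timestamps = np.asarray(self.timestamps, dtype=float)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n, h, w) array")
        if len(self.timestamps) != len(self.frames):
            raise ValueError("one timestamp per frame required")
        if len(self.timestamps) > 1 and np.any(np.diff(self.timestamps) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.missing is None:
            self.missing = np.zeros(len(self.frames), dtype=bool)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]


@dataclass(frozen=True)
class ROI:
    """Rectangle in pixel coordinates, 0-based, half-open [x0,x1) x [y0,y1)."""

    x0: int
    y0: int
    x1: int
    y1: int
    label: str = ""          # "background" or "<subgroup>"
    cell_id: str = ""
    brain_id: str = ""

    def mean_in(self, frame: np.ndarray) -> float:
        return float(frame[self.y0:self.y1, self.x0:self.x1].mean())


@dataclass
class ROISet:
    cells: list[ROI]
    background: ROI

    def validate(self, shape: tuple[int, int]) -> None:
        h, w = shape
        for roi in [*self.cells, self.background]:
            if not (0 <= roi.x0 < roi.x1 <= w and 0 <= roi.y0 < roi.y1 <= h):
                raise ValueError(f"ROI {roi} outside frame bounds {shape}")

    def to_csv(self, path) -> None:
        import csv
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["x0", "y0", "x1", "y1", "label", "cell_id", "brain_id"])
            for roi in [*self.cells, self.background]:
                w.writerow([roi.x0, roi.y0, roi.x1, roi.y1, roi.label, roi.cell_id, roi.brain_id])

    @classmethod
    def from_csv(cls, path) -> "ROISet":
        import csv
        cells, background = [], None
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                roi = ROI(int(row["x0"]), int(row["y0"]), int(row["x1"]), int(row["y1"]),
                          row["label"], row["cell_id"], row["brain_id"])
                if roi.label == "background":
                    background = roi
                else:
                    cells.append(roi)
        if background is None:
            raise ValueError("ROI file lacks a background ROI")
        return cls(cells, background)


def filter_cosmic_rays(
    stack: FrameStack,
    pixel_threshold: float = 800.0,
    sd_mult: float = 3.0,
    window: int = 30,
    mode: str = "above",
) -> tuple[FrameStack, list[int]]:
    """Reject frames hit by cosmic rays.

    Per frame the statistic S is the sum of pixel values exceeding
    ``pixel_threshold`` (``mode="above"``; ``mode="total"`` instead uses the
    total frame sum when it exceeds the threshold).  A frame is rejected when
    its S exceeds the mean by more than ``sd_mult`` standard deviations, both
    computed over the trailing ``window`` previously *accepted* frames, so a
    ray cannot inflate the running statistics and mask the next one.  The
    first ``window`` frames are a warm-up and are never rejected.
    """
    if len(stack) == 0:
        raise ValueError("empty stack")
    if window < 2:
        raise ValueError("window must be >= 2")

    if mode == "above":
        s = np.array([f[f > pixel_threshold].sum() for f in stack.frames])
    elif mode == "total":
        tot = stack.frames.sum(axis=(1, 2))
        s = np.where(tot > pixel_threshold, tot, 0.0)
    else:
        raise ValueError("mode must be 'above' or 'total'")

    accepted: list[int] = []
    rejected: list[int] = []
    recent: list[float] = []
    for j in range(len(stack)):
        if len(accepted) >= window:
            buf = np.array(recent[-window:])
            if s[j] > buf.mean() + sd_mult * buf.std():
                rejected.append(j)
                continue
        accepted.append(j)
        recent.append(s[j])

    out = FrameStack(
        stack.frames[accepted], stack.timestamps[accepted], stack.exposure_min,
        stack.missing[accepted],
    )
    return out, rejected


def bin_frames(stack: FrameStack, bin_minutes: float = 45.0) -> FrameStack:
    """Pixelwise-average frames into half-open time bins.

    Bins are anchored at t = 0 with width ``bin_minutes``; the output
    timestamp is the bin midpoint.  Bins containing no frames are emitted as
    missing (NaN frames with the missing flag set), not as zeros.
    """
    if bin_minutes <= 0:
        raise ValueError("bin_minutes must be > 0")
    if len(stack) == 0:
        raise ValueError("empty stack")
    bw = bin_minutes / 60.0
    idx = np.floor(stack.timestamps / bw).astype(int)
    first, last = idx.min(), idx.max()
    n_bins = last - first + 1
    h, w = stack.shape
    frames = np.full((n_bins, h, w), np.nan)
    missing = np.ones(n_bins, dtype=bool)
    for b in range(first, last + 1):
        sel = idx == b
        if sel.any():
            frames[b - first] = stack.frames[sel].mean(axis=0)
            missing[b - first] = False
    midpoints = (np.arange(first, last + 1) + 0.5) * bw
    return FrameStack(frames, midpoints, stack.exposure_min, missing)


def running_minimum(stack: FrameStack) -> FrameStack:
    """Pixelwise minimum of sequential frame pairs.

    Output frame j = min(frame j, frame j+1), stamped at frame j's time;
    single-frame transients (hot pixels, residual cosmic rays) vanish from
    both frames they would otherwise touch.  A pair involving a missing bin
    is itself missing.
    """
    if len(stack) < 2:
        raise ValueError("running minimum needs at least 2 frames")
    frames = np.minimum(stack.frames[:-1], stack.frames[1:])
    missing = stack.missing[:-1] | stack.missing[1:]
    frames = np.where(missing[:, None, None], np.nan, frames)
    return FrameStack(frames, stack.timestamps[:-1], stack.exposure_min, missing)


def extract_traces(stack: FrameStack, rois: ROISet) -> list[CellTrace]:
    """Mean intensity per cell ROI minus the same frame's background ROI mean.

    Background varies per frame, so values may be negative; missing bins
    propagate as NaN samples flagged missing.
    """
    rois.validate(stack.shape)
    bg = np.array([rois.background.mean_in(f) for f in stack.frames])
    out = []
    for roi in rois.cells:
        vals = np.array([roi.mean_in(f) for f in stack.frames]) - bg
        out.append(
            CellTrace(
                cell_id=roi.cell_id or roi.label,
                brain_id=roi.brain_id,
                subgroup=roi.label,
                t=stack.timestamps,
                y=vals,
                units="intensity",
                missing=stack.missing.copy(),
            )
        )
    return out


def to_photons_per_minute(
    trace: CellTrace, calibration_scale: float = 1.0, exposure_min: float = 15.0
) -> CellTrace:
    """Convert raw integrated intensity to photons per minute."""
    if calibration_scale <= 0:
        raise ValueError("calibration_scale must be > 0")
    return CellTrace(
        trace.cell_id, trace.brain_id, trace.subgroup,
        trace.t, trace.y * calibration_scale / exposure_min,
        trace.reporter, "photons/min", trace.missing,
    )


def write_stack(stack: FrameStack, path) -> None:
    """Write a multi-page TIFF plus timestamps as image descriptions."""
    import tifffile
    tifffile.imwrite(
        path,
        stack.frames.astype(np.float32),
        metadata={"timestamps_h": stack.timestamps.tolist(),
                  "exposure_min": stack.exposure_min},
    )


def read_stack(path, exposure_min: float | None = None) -> FrameStack:
    import json
    import tifffile
    with tifffile.TiffFile(path) as tf:
        frames = tf.asarray()
        meta = tf.shaped_metadata[0] if tf.shaped_metadata else {}
    ts = np.asarray(meta.get("timestamps_h", np.arange(len(frames)) * 0.25), dtype=float)
    exp = exposure_min if exposure_min is not None else float(meta.get("exposure_min", 15.0))
    return FrameStack(frames, ts, exp)
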
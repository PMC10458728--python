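"""Per-frame insect pose (centroid, yaw) and dynamic gap width extraction.

Works on high-speed (163 fps) sequences.  The insect is segmented against a
background model and its orientation estimated from the second central
moments of the contour (equivalent-ellipse axis); the 180-degree axis
ambiguity is resolved toward the direction of motion.  The barrier gap is
measured inside a fixed region of interest: the bright (open) area's pixel
count A_s is converted to metres through the calibration pair (A_max, d_max)
as d_s = (A_s / A_max) * d_max — valid because the gap's vertical extent is
constant, so area is proportional to horizontal width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic_imaging import FrameSequence
from .trigger import MedianBackgroundModel, segment_foreground

__all__ = [
    "GapROI",
    "PoseTrack",
    "TrackConfig",
    "estimate_yaw",
    "gap_width_from_roi",
    "track_pose",
]


@dataclass
class GapROI:
    """Image rectangle covering the barrier gap, with area calibration."""

    x: int
    y: int
    w: int
    h: int
    amax: float  # px^2, gap area at full opening
    dmax: float  # m, gap width at full opening
    threshold: float = 130.0  # gray level separating panels from the open gap

    def __post_init__(self) -> None:
        if self.amax <= 0:
            raise ValueError("Amax must be positive")
        if self.w <= 0 or self.h <= 0:
            raise ValueError("ROI must have positive extent")

    def crop(self, frame: np.ndarray) -> np.ndarray:
        return frame[self.y : self.y + self.h, self.x : self.x + self.w]


def gap_width_from_roi(frame: np.ndarray, roi: GapROI) -> tuple[float, bool]:
    """Decode the gap width d_s = (A_s / A_max) * d_max from one frame.

    The bright region inside the ROI is segmented at ``roi.threshold``; A_s is
    the pixel area of its largest connected component.  Returns (d_s, ok);
    ``ok`` is False when no bright component is found (d_s = 0, warning case).
    The result is clipped to [0, d_max].
    """
    patch = roi.crop(np.asarray(frame, dtype=float))
    bright = patch > roi.threshold
    labels, n = ndimage.label(bright)
    if n == 0:
        return 0.0, False
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    a_s = float(areas.max())
    d_s = (a_s / roi.amax) * roi.dmax
    return float(np.clip(d_s, 0.0, roi.dmax)), True


def calibrate_gap_roi(
    open_frame: np.ndarray,
    rect: tuple[int, int, int, int],
    dmax: float,
    threshold: float = 130.0,
) -> GapROI:
    """Build a :class:`GapROI` from a frame captured at full gap opening."""
    x, y, w, h = rect
    roi = GapROI(x, y, w, h, amax=1.0, dmax=dmax, threshold=threshold)
    patch = roi.crop(np.asarray(open_frame, dtype=float))
    bright = patch > threshold
    labels, n = ndimage.label(bright)
    if n == 0:
        raise ValueError("no bright gap region in the calibration frame")
    areas = ndimage.sum_labels(np.ones_like(labels), labels, np.arange(1, n + 1))
    roi.amax = float(areas.max())
    return roi


def estimate_yaw(mask: np.ndarray) -> tuple[float, bool]:
    """Orientation of the equivalent ellipse of the (single) contour in ``mask``.

    theta = 0.5 * atan2(2*mu11, mu20 - mu02) in image coordinates (x = columns
    rightward, y = rows downward), returned in degrees in (-90, 90].  The
    second return value is False for degenerate (near-circular) blobs where
    the orientation is undefined.
    """
    mask = np.asarray(mask).astype(bool)
    ys, xs = np.nonzero(mask)
    if len(xs) == 0:
        raise ValueError("empty mask")
    x0, y0 = xs.mean(), ys.mean()
    mu20 = np.mean((xs - x0) ** 2)
    mu02 = np.mean((ys - y0) ** 2)
    mu11 = np.mean((xs - x0) * (ys - y0))
    aniso = math.hypot(mu20 - mu02, 2 * mu11)
    confident = aniso > 0.05 * (mu20 + mu02)
    theta = 0.5 * math.atan2(2.0 * mu11, mu20 - mu02)
    deg = math.degrees(theta)
    if deg <= -90.0:
        deg += 180.0
    return deg, confident


def _disambiguate_yaw(axis_deg: float, heading_deg: float) -> float:
    """Pick axis_deg or axis_deg+180 so the result points along the heading."""
    cand = (axis_deg + 180.0) % 360.0 - 180.0
    diff = (cand - heading_deg + 180.0) % 360.0 - 180.0
    if abs(diff) > 90.0:
        cand = (cand + 180.0 + 180.0) % 360.0 - 180.0
    return cand


@dataclass
class TrackConfig:
    area_limits: tuple[float, float] = (50.0, 5000.0)
    background_threshold: float = 30.0
    n_background_frames: int = 20  # evenly sampled across the sequence
    background: np.ndarray | None = None  # explicit background, optional
    exclude_roi: tuple[int, int, int, int] | None = None  # mask out barrier band


@dataclass
class PoseTrack:
    """Per-frame time series of insect pose and gap width (the central
    exchange format of the pipeline)."""

    frame: np.ndarray  # (N,) int
    time_s: np.ndarray  # (N,) = frame / fps
    cx_px: np.ndarray
    cy_px: np.ndarray
    yaw_deg: np.ndarray  # (-180, 180], NaN where invalid
    gap_m: np.ndarray
    valid: np.ndarray  # bool
    fps: float = 163.0

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame": self.frame,
                "time_s": self.time_s,
                "cx_px": self.cx_px,
                "cy_px": self.cy_px,
                "yaw_deg": self.yaw_deg,
                "gap_m": self.gap_m,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, fps: float = 163.0) -> "PoseTrack":
        df = pd.read_csv(path)
        return cls(
            df["frame"].to_numpy(),
            df["time_s"].to_numpy(),
            df["cx_px"].to_numpy(),
            df["cy_px"].to_numpy(),
            df["yaw_deg"].to_numpy(),
            df["gap_m"].to_numpy(),
            df["valid"].to_numpy().astype(bool),
            fps=fps,
        )


def track_pose(
    seq: FrameSequence,
    config: TrackConfig | None = None,
    gap_roi: GapROI | None = None,
) -> PoseTrack:
    """Extract the insect pose track (and gap series) from a sequence.

    Per frame: background subtraction, single-contour centroid, moment-based
    yaw; frames with no or ambiguous detection are marked invalid.  Yaw is
    axis-disambiguated toward the centroid motion in a second pass.  When
    ``gap_roi`` is given the gap width is decoded per frame; otherwise the
    gap column is NaN.
    """
    config = config or TrackConfig()
    if len(seq) < 2:
        raise ValueError("sequence must contain at least 2 frames")
    model = MedianBackgroundModel(config.background_threshold)
    if config.background is not None:
        model.background = np.asarray(config.background, dtype=float)
    else:
        # median over frames sampled across the whole sequence: the moving
        # insect occupies any given pixel in only a minority of them
        step = max(len(seq) // config.n_background_frames, 1)
        model.warmup(seq.frames[::step])
    exclude = None
    if config.exclude_roi is not None:
        x, y, w, h = config.exclude_roi
        exclude = np.zeros(seq.frames[0].shape, dtype=bool)
        exclude[y : y + h, x : x + w] = True

    n = len(seq)
    cx = np.full(n, np.nan)
    cy = np.full(n, np.nan)
    yaw_axis = np.full(n, np.nan)
    gap = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    for k, frame in enumerate(seq.frames):
        if gap_roi is not None:
            gap[k], _ = gap_width_from_roi(frame, gap_roi)
        mask = segment_foreground(frame, model).astype(bool)
        if exclude is not None:
            mask = mask & ~exclude
        labels, nlab = ndimage.label(mask)
        if nlab == 0:
            continue
        areas = ndimage.sum_labels(
            np.ones_like(labels), labels, np.arange(1, nlab + 1)
        )
        lo, hi = config.area_limits
        keep = np.nonzero((areas >= lo) & (areas <= hi))[0]
        if len(keep) != 1:  # none or ambiguous -> invalid frame
            continue
        blob = labels == int(keep[0]) + 1
        ys, xs = np.nonzero(blob)
        hh, ww = mask.shape
        if xs.min() == 0 or ys.min() == 0 or xs.max() == ww - 1 or ys.max() == hh - 1:
            continue  # clipped at the image border: centroid would be biased
        if config.exclude_roi is not None:
            # a blob clipped by the exclusion rectangle has a biased
            # centroid: mark the frame invalid instead
            x, y, w, h = config.exclude_roi
            if (
                xs.min() <= x + w
                and xs.max() >= x - 1
                and ys.min() <= y + h
                and ys.max() >= y - 1
            ):
                continue
        cx[k], cy[k] = xs.mean(), ys.mean()
        axis, confident = estimate_yaw(blob)
        yaw_axis[k] = axis if confident else np.nan
        valid[k] = True
    if not valid.any():
        raise ValueError("no valid frames in sequence")

    # second pass: resolve the 180-degree ambiguity toward motion direction
    yaw = np.full(n, np.nan)
    idx = np.nonzero(valid)[0]
    last_yaw = None
    for j, k in enumerate(idx):
        if j + 1 < len(idx):
            k2 = idx[j + 1]
            heading = math.degrees(math.atan2(cy[k2] - cy[k], cx[k2] - cx[k]))
        elif j > 0:
            k1 = idx[j - 1]
            heading = math.degrees(math.atan2(cy[k] - cy[k1], cx[k] - cx[k1]))
        else:
            heading = 0.0
        if np.isnan(yaw_axis[k]):
            yaw[k] = last_yaw if last_yaw is not None else heading
        else:
            yaw[k] = _disambiguate_yaw(yaw_axis[k], heading)
        last_yaw = yaw[k]

    frames_idx = np.arange(n)
    return PoseTrack(
        frames_idx,
        frames_idx / seq.fps,
        cx,
        cy,
        yaw,
        gap,
        valid,
        fps=seq.fps,
    )
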
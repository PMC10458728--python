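"""Direction-gated automatic trigger.

The detection camera watches the tunnel at low rate (30 fps).  Every frame is
background-subtracted, the insect contour's centroid is extracted and its
x-pixel coordinate pushed into a fixed-length queue.  Once the queue is full
the mean per-frame displacement

    PxS = sum_i (Px_i - Px_{i-1}) / n = (Px_last - Px_first) / n

is computed; its sign encodes the crossing direction along image x.  A signed
counter (Flag) accumulates the sign of PxS frame by frame, and when the
insect has completely left the field of view the trigger fires if and only if
Flag indicates the configured direction.

Fast crossings can leave the field before the queue ever fills (above
~8 m/s a 620 mm field at 30 fps yields fewer than 3 detection frames).  In
that case the exit decision falls back to the same statistic computed over
all detections of the crossing, which needs only two frames; with fewer than
two detections no decision is possible and the trigger stays silent.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

__all__ = [
    "MedianBackgroundModel",
    "segment_foreground",
    "extract_centroid",
    "AmbiguousDetection",
    "direction_statistic",
    "TriggerConfig",
    "TriggerState",
    "update_trigger",
    "run_trigger",
]


class AmbiguousDetection(Exception):
    """More than one qualifying contour: multiple-insect guard."""


class MedianBackgroundModel:
    """Static background estimate: pixelwise median over warm-up frames.

    Deterministic and sufficient for a fixed camera over a fixed scene; an
    adaptive mixture model can be substituted behind the same interface.
    """

    def __init__(self, threshold: float = 30.0):
        self.threshold = threshold
        self.background: np.ndarray | None = None

    def warmup(self, frames) -> "MedianBackgroundModel":
        frames = np.asarray(frames)
        if frames.ndim == 2:
            frames = frames[None]
        if len(frames) == 0:
            raise ValueError("need at least one warm-up frame")
        self.background = np.median(frames.astype(float), axis=0)
        return self

    def apply(self, frame: np.ndarray) -> np.ndarray:
        if self.background is None:
            raise RuntimeError("background model not warmed up")
        frame = np.asarray(frame, dtype=float)
        if frame.shape != self.background.shape:
            raise ValueError(
                f"frame shape {frame.shape} != model shape {self.background.shape}"
            )
        return (np.abs(frame - self.background) > self.threshold).astype(np.uint8)


def segment_foreground(frame: np.ndarray, model: MedianBackgroundModel) -> np.ndarray:
    """Binary foreground mask: pixels deviating from the background estimate."""
    return model.apply(frame)


def extract_centroid(
    mask: np.ndarray,
    area_limits: tuple[float, float] = (50.0, 5000.0),
    exclude: np.ndarray | None = None,
) -> tuple[float, float] | None:
    """Centroid (x_px, y_px) of the single qualifying contour in ``mask``.

    Connected components are filtered by area to ``area_limits``; returns
    None when no component qualifies and raises :class:`AmbiguousDetection`
    when more than one does (the single-insect guard).  ``exclude`` is an
    optional boolean mask of pixels to ignore (e.g. the barrier ROI).
    """
    mask = np.asarray(mask).astype(bool)
    if exclude is not None:
        mask = mask & ~np.asarray(exclude).astype(bool)
    labels, n = ndimage.label(mask)
    if n == 0:
        return None
    lo, hi = area_limits
    areas = ndimage.sum_labels(np.ones_like(labels), labels, index=np.arange(1, n + 1))
    keep = np.nonzero((areas >= lo) & (areas <= hi))[0]
    if len(keep) == 0:
        return None
    if len(keep) > 1:
        raise AmbiguousDetection(f"{len(keep)} qualifying contours")
    cy, cx = ndimage.center_of_mass(mask, labels, index=int(keep[0]) + 1)
    return float(cx), float(cy)


def direction_statistic(queue) -> float:
    """PxS over a full queue: mean per-frame x displacement, (last-first)/n.

    Requires the queue to be full by construction of the caller; fewer than
    two entries raise (no decision possible).
    """
    q = list(queue)
    n = len(q)
    if n < 2:
        raise ValueError("direction statistic needs a full queue (n >= 2)")
    return (q[-1] - q[0]) / n


@dataclass
class TriggerConfig:
    direction: str = "+x"  # fire for crossings toward +x or -x in image coords
    queue_len: int = 5
    area_limits: tuple[float, float] = (50.0, 5000.0)
    flag_threshold: int = 1
    exit_patience: int = 3  # consecutive empty frames = insect has left


@dataclass
class TriggerEvent:
    fire_frame: int
    mean_pxs: float
    n_detection_frames: int


@dataclass
class TriggerState:
    """Per-crossing state of the trigger pipeline."""

    config: TriggerConfig = field(default_factory=TriggerConfig)
    queue: deque = field(init=False)
    flag: int = 0
    detections: list = field(default_factory=list)  # x centroids of this crossing
    frames_since_seen: int = 0
    frame_index: int = -1
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.config.direction not in ("+x", "-x"):
            raise ValueError("direction must be '+x' or '-x'")
        if self.config.queue_len < 2:
            raise ValueError("queue length must be >= 2")
        self.queue = deque(maxlen=self.config.queue_len)

    def _reset_crossing(self) -> None:
        self.queue.clear()
        self.flag = 0
        self.detections = []
        self.frames_since_seen = 0

    def push_detection(self, centroid: tuple[float, float] | None) -> str | None:
        """Advance one frame with a detection result (or None).

        Returns "fire" when the configured-direction crossing completes,
        else None.  Ambiguous frames should simply be skipped by the caller
        (state preserved).
        """
        self.frame_index += 1
        cfg = self.config
        if centroid is not None:
            x = centroid[0]
            self.detections.append(x)
            self.queue.append(x)
            self.frames_since_seen = 0
            if len(self.queue) == self.queue.maxlen:
                pxs = direction_statistic(self.queue)
                if pxs > 0:
                    self.flag += 1
                elif pxs < 0:
                    self.flag -= 1
            return None
        if not self.detections:
            return None
        self.frames_since_seen += 1
        if self.frames_since_seen >= cfg.exit_patience:
            return self._decide()
        return None

    def finalize(self) -> str | None:
        """End of sequence: decide on any crossing still in progress."""
        if self.detections:
            return self._decide()
        return None

    def _decide(self) -> str | None:
        cfg = self.config
        flag = self.flag
        if flag == 0 and len(self.detections) >= 2:
            # queue never filled (fast crossing): same statistic over all
            # detections of the crossing
            pxs = (self.detections[-1] - self.detections[0]) / len(self.detections)
            flag = 1 if pxs > 0 else (-1 if pxs < 0 else 0)
        n_det = len(self.detections)
        mean_pxs = (
            (self.detections[-1] - self.detections[0]) / n_det if n_det >= 2 else 0.0
        )
        fire = (cfg.direction == "+x" and flag >= cfg.flag_threshold) or (
            cfg.direction == "-x" and flag <= -cfg.flag_threshold
        )
        self._reset_crossing()
        if fire:
            self.events.append(TriggerEvent(self.frame_index, mean_pxs, n_det))
            return "fire"
        return None


def update_trigger(
    state: TriggerState, frame: np.ndarray, model: MedianBackgroundModel
) -> str | None:
    """Full per-frame pipeline: segment -> centroid -> queue -> Flag -> decision."""
    mask = segment_foreground(frame, model)
    try:
        centroid = extract_centroid(mask, state.config.area_limits)
    except AmbiguousDetection:
        state.frame_index += 1  # frame consumed, state otherwise preserved
        return None
    return state.push_detection(centroid)


def run_trigger(
    frames,
    model: MedianBackgroundModel,
    config: TriggerConfig | None = None,
) -> list[TriggerEvent]:
    """Run the trigger over a frame stack and return all capture events."""
    state = TriggerState(config or TriggerConfig())
    for frame in frames:
        update_trigger(state, frame, model)
    state.finalize()
    return state.events
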
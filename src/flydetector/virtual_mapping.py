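"""Virtual mapping: pixel tracks -> world-coordinate tracks on the flight plane.

A single overhead camera cannot recover height, so every pixel is
back-projected onto an assumed flight plane at mid-tunnel height (the same
planar assumption the physical rig makes).  Mapping fidelity is quantified by
re-projecting the world track to pixels and measuring per-point errors
against the detected pixel track (the round-trip check).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .camera import CameraModel
from .pose_gap import PoseTrack

__all__ = [
    "CameraCalibration",
    "WorldTrack",
    "pixel_to_world",
    "world_to_pixel",
    "map_track",
    "roundtrip_error",
]


@dataclass
class CameraCalibration:
    """A camera model plus the assumed flight-plane height."""

    camera: CameraModel
    flight_plane_z: float = 0.14  # mid-tunnel for the default 0.28 m tunnel

    @classmethod
    def from_yaml(cls, path, flight_plane_z: float | None = None) -> "CameraCalibration":
        cam = CameraModel.from_yaml(path)
        if flight_plane_z is None:
            flight_plane_z = 0.14
        return cls(cam, flight_plane_z)


def pixel_to_world(cal: CameraCalibration, p) -> np.ndarray:
    """Back-project pixel(s) onto the flight plane (pinhole ray casting)."""
    return cal.camera.pixel_to_world(p, cal.flight_plane_z)


def world_to_pixel(cal: CameraCalibration, p) -> np.ndarray:
    """Project world point(s) to pixels."""
    return cal.camera.world_to_pixel(p)


@dataclass
class WorldTrack:
    """World-frame trajectory at the assumed flight-plane height."""

    time_s: np.ndarray
    x_m: np.ndarray
    y_m: np.ndarray
    z_m: np.ndarray
    yaw_deg: np.ndarray
    gap_m: np.ndarray
    valid: np.ndarray

    def __len__(self) -> int:
        return len(self.time_s)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_m, self.y_m, self.z_m])

    def out_of_bounds(self, scene) -> np.ndarray:
        """Flag samples outside the tunnel box (flagged, never dropped)."""
        return ~np.array(
            [scene.contains(p) if v else False for p, v in zip(self.positions, self.valid)]
        ) & self.valid

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "x_m": self.x_m,
                "y_m": self.y_m,
                "z_m": self.z_m,
                "yaw_deg": self.yaw_deg,
                "gap_m": self.gap_m,
                "valid": self.valid.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "WorldTrack":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df["x_m"].to_numpy(),
            df["y_m"].to_numpy(),
            df["z_m"].to_numpy(),
            df["yaw_deg"].to_numpy(),
            df["gap_m"].to_numpy(),
            df["valid"].to_numpy().astype(bool),
        )


def map_track(track: PoseTrack, cal: CameraCalibration) -> WorldTrack:
    """Map a pixel-space pose track into world coordinates.

    Invalid frames are propagated as gaps (NaN positions, valid=False); yaw
    is converted from the image convention (v down) to the world convention
    (y left-positive), i.e. negated for a nadir camera.
    """
    if not np.any(track.valid):
        raise ValueError("track has no valid frames")
    n = len(track)
    x = np.full(n, np.nan)
    y = np.full(n, np.nan)
    z = np.full(n, np.nan)
    yaw = np.full(n, np.nan)
    idx = np.nonzero(track.valid)[0]
    uv = np.column_stack([track.cx_px[idx], track.cy_px[idx]])
    pw = pixel_to_world(cal, uv)
    x[idx], y[idx], z[idx] = pw[:, 0], pw[:, 1], pw[:, 2]
    yaw[idx] = [cal.camera.yaw_world_from_image(a) for a in track.yaw_deg[idx]]
    return WorldTrack(
        track.time_s.copy(), x, y, z, yaw, track.gap_m.copy(), track.valid.copy()
    )


def roundtrip_error(
    track: PoseTrack, world: WorldTrack, cal: CameraCalibration
) -> dict:
    """Per-point pixel error between the detected track and the re-projected
    world track.

    Returns a dict with keys ``per_point`` (Euclidean, NaN on invalid frames),
    ``per_axis`` ((N, 2) signed errors), ``max`` and ``mean``.
    """
    if len(track) != len(world):
        raise ValueError("track and world track must have equal length")
    n = len(track)
    per_point = np.full(n, np.nan)
    per_axis = np.full((n, 2), np.nan)
    idx = np.nonzero(track.valid & world.valid)[0]
    if len(idx) == 0:
        raise ValueError("no jointly valid frames")
    pw = np.column_stack([world.x_m[idx], world.y_m[idx], world.z_m[idx]])
    uv = world_to_pixel(cal, pw)
    du = uv[:, 0] - track.cx_px[idx]
    dv = uv[:, 1] - track.cy_px[idx]
    per_axis[idx, 0], per_axis[idx, 1] = du, dv
    per_point[idx] = np.hypot(du, dv)
    return {
        "per_point": per_point,
        "per_axis": per_axis,
        "max": float(np.nanmax(per_point)),
        "mean": float(np.nanmean(per_point)),
    }
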
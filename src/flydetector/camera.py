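"""Pinhole camera model shared by the renderer and the virtual mapping.

Cameras look down at the tunnel from above.  The camera frame is chosen so
that image ``u`` (columns, rightward) increases with world ``x`` and image
``v`` (rows, downward) increases as world ``y`` decreases — i.e. on screen the
insect flies left-to-right and "up" in the image is the world's left.  Because
image v points down while world y points left, a heading measured in image
coordinates is the negative of the world yaw.

An optional ``tilt_deg`` pitches the optical axis away from straight-down
about the camera's v axis, which is how the oblique-view (height-loss) case
is constructed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import yaml

__all__ = ["CameraModel"]


def _rot_y(deg: float) -> np.ndarray:
    c, s = math.cos(math.radians(deg)), math.sin(math.radians(deg))
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


@dataclass
class CameraModel:
    """Top-down pinhole camera.

    Parameters
    ----------
    image_size : (width, height) in pixels.
    focal_px : focal length in pixels (square pixels assumed).
    position : camera centre (x, y, z) in world metres.
    tilt_deg : pitch of the optical axis about the camera v axis; 0 = nadir.
    fps : frame rate, carried along for sequence bookkeeping.
    """

    image_size: tuple[int, int]
    focal_px: float
    position: tuple[float, float, float]
    tilt_deg: float = 0.0
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.focal_px <= 0:
            raise ValueError("focal length must be positive")
        # world->camera rotation: rows are the camera axes in world coords.
        # Nadir orientation: u ~ +x, v ~ -y, optical axis ~ -z.
        base = np.array([[1.0, 0.0, 0.0], [0.0, -1.0, 0.0], [0.0, 0.0, -1.0]])
        self._R = _rot_y(self.tilt_deg) @ base

    # -- constructors ------------------------------------------------------

    @classmethod
    def from_fov(
        cls,
        image_size: tuple[int, int],
        fov_deg: tuple[float, float],
        position: tuple[float, float, float],
        tilt_deg: float = 0.0,
        fps: float = 30.0,
    ) -> "CameraModel":
        """Camera from horizontal/vertical field-of-view angles in degrees."""
        fov_h, fov_v = fov_deg
        if not (0.0 < fov_h < 180.0 and 0.0 < fov_v < 180.0):
            raise ValueError("field of view must be in (0, 180) degrees")
        focal = (image_size[0] / 2.0) / math.tan(math.radians(fov_h) / 2.0)
        return cls(image_size, focal, position, tilt_deg, fps)

    @classmethod
    def from_field_width(
        cls,
        image_size: tuple[int, int],
        field_width_m: float,
        position: tuple[float, float, float],
        plane_z: float,
        fps: float = 30.0,
    ) -> "CameraModel":
        """Nadir camera whose horizontal footprint on the plane ``z=plane_z``
        spans ``field_width_m`` metres across the full image width."""
        h_above = position[2] - plane_z
        if h_above <= 0:
            raise ValueError("camera must be above the target plane")
        focal = image_size[0] * h_above / field_width_m
        return cls(image_size, focal, position, 0.0, fps)

    # -- projection --------------------------------------------------------

    @property
    def principal_point(self) -> tuple[float, float]:
        return ((self.image_size[0] - 1) / 2.0, (self.image_size[1] - 1) / 2.0)

    def world_to_pixel(self, p) -> np.ndarray:
        """Project world point(s) (..., 3) to pixel coordinates (..., 2)."""
        p = np.asarray(p, dtype=float)
        pc = (p - np.asarray(self.position)) @ self._R.T
        z = pc[..., 2]
        if np.any(z <= 0):
            raise ValueError("point is behind the camera")
        cx, cy = self.principal_point
        u = cx + self.focal_px * pc[..., 0] / z
        v = cy + self.focal_px * pc[..., 1] / z
        return np.stack([u, v], axis=-1)

    def pixel_to_world(self, uv, plane_z: float) -> np.ndarray:
        """Back-project pixel(s) (..., 2) onto the horizontal plane z=plane_z."""
        uv = np.asarray(uv, dtype=float)
        cx, cy = self.principal_point
        d_cam = np.stack(
            [
                (uv[..., 0] - cx) / self.focal_px,
                (uv[..., 1] - cy) / self.focal_px,
                np.ones(uv.shape[:-1]),
            ],
            axis=-1,
        )
        d_world = d_cam @ self._R  # R^T applied to each ray
        dz = d_world[..., 2]
        if np.any(np.abs(dz) < 1e-12):
            raise ValueError("ray parallel to the flight plane; no intersection")
        t = (plane_z - self.position[2]) / dz
        return np.asarray(self.position) + t[..., None] * d_world

    def meters_per_pixel(self, plane_z: float) -> float:
        """Ground sampling distance at ``plane_z`` for the nadir case."""
        return (self.position[2] - plane_z) / self.focal_px

    def yaw_world_from_image(self, yaw_image_deg: float) -> float:
        """Convert an image-frame heading to world yaw (v down vs y left)."""
        yaw = -yaw_image_deg
        return (yaw + 180.0) % 360.0 - 180.0

    # -- io ----------------------------------------------------------------

    def to_yaml(self, path) -> None:
        doc = {
            "image_size": list(self.image_size),
            "focal_px": float(self.focal_px),
            "position": list(self.position),
            "tilt_deg": float(self.tilt_deg),
            "fps": float(self.fps),
        }
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "CameraModel":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls(
            tuple(doc["image_size"]),
            doc["focal_px"],
            tuple(doc["position"]),
            doc.get("tilt_deg", 0.0),
            doc.get("fps", 30.0),
        )
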
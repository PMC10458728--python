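"""Seeded synthetic imaging: flight simulation and tunnel-scene rendering.

Replaces the physical rig (detector camera at 30 fps, high-speed framing
camera at 163 fps) with a deterministic renderer.  Frames are top-down
grayscale views of the tunnel: a light floor with the 1/f wall pattern shown
as bands along the image edges, the barrier drawn as two dark panels leaving
the time-varying gap, and the insect drawn as an oriented dark ellipse (major
axis = body length, rotated by yaw).  All randomness flows from explicit
seeds, so any sequence can be regenerated exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .camera import CameraModel
from .scene_model import BarrierKinematics, TunnelScene, gap_at_time

__all__ = [
    "FlightProfile",
    "GroundTruthTrack",
    "FrameSequence",
    "simulate_flight",
    "render_sequence",
    "render_frame",
    "detector_camera",
    "highspeed_camera",
    "default_gap_roi",
]

# grayscale levels used by the renderer
FLOOR_LEVEL = 200
PANEL_LEVEL = 60
INSECT_LEVEL = 30
TEXTURE_DARK = 120
TEXTURE_LIGHT = 230
BARRIER_THICKNESS_M = 0.02


def detector_camera(
    scene: TunnelScene,
    image_size: tuple[int, int] = (960, 360),
    field_width_m: float = 0.62,
    fps: float = 30.0,
    height_above: float = 1.0,
) -> CameraModel:
    """The wide-angle detection camera: 30 fps, 620 mm horizontal footprint,
    mounted nadir over the centre of the tunnel."""
    pos = (scene.length / 2.0, 0.0, height_above)
    return CameraModel.from_field_width(
        image_size, field_width_m, pos, scene.flight_plane_z, fps=fps
    )


def highspeed_camera(
    scene: TunnelScene,
    image_size: tuple[int, int] = (640, 480),
    fov_deg: tuple[float, float] = (46.8, 36.0),
    fps: float = 163.0,
    height: float = 0.6,
    center_x: float | None = None,
) -> CameraModel:
    """The high-speed framing camera: 163 fps, 46.8 x 36 degree field of view,
    mounted nadir over the barrier region."""
    cx = scene.barrier_plane_x if center_x is None else center_x
    return CameraModel.from_fov(image_size, fov_deg, (cx, 0.0, height), fps=fps)


@dataclass
class FlightProfile:
    """Parameters of a simulated tunnel passage."""

    speed: float = 1.0  # mean forward speed, m/s
    duration: float = 1.0  # s
    start: tuple[float, float, float] | None = None  # default: entrance, axis, mid-height
    lateral_amplitude: float = 0.0  # m, amplitude of the scanning oscillation
    lateral_freq_hz: float = 2.0
    noise_std: float = 0.0  # m, smooth positional jitter
    sample_rate: float = 163.0  # Hz
    body_length: float = 0.013  # m
    body_width: float = 0.004  # m


@dataclass
class GroundTruthTrack:
    """Known flight trajectory: times, world positions, yaw, body size."""

    times: np.ndarray  # (N,), s, strictly increasing
    positions: np.ndarray  # (N, 3), m
    yaw_deg: np.ndarray  # (N,), heading in the x-y plane, (-180, 180]
    body_length: float = 0.013
    body_width: float = 0.004

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.yaw_deg = np.asarray(self.yaw_deg, dtype=float)
        if len(self.times) == 0:
            raise ValueError("track must contain at least one sample")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("track times must be strictly increasing")

    @property
    def velocities(self) -> np.ndarray:
        """Finite-difference linear velocity, (N, 3) in m/s."""
        if len(self.times) < 2:
            return np.zeros_like(self.positions)
        return np.gradient(self.positions, self.times, axis=0)

    def at(self, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Interpolate (positions, yaw_deg) at times ``t`` (no extrapolation:
        clamped to the track's endpoints)."""
        t = np.atleast_1d(np.asarray(t, dtype=float))
        pos = np.column_stack(
            [np.interp(t, self.times, self.positions[:, k]) for k in range(3)]
        )
        unwrapped = np.unwrap(np.radians(self.yaw_deg))
        yaw = np.degrees(np.interp(t, self.times, unwrapped))
        yaw = (yaw + 180.0) % 360.0 - 180.0
        return pos, yaw

    def to_csv(self, path) -> None:
        pd.DataFrame(
            {
                "time_s": self.times,
                "x_m": self.positions[:, 0],
                "y_m": self.positions[:, 1],
                "z_m": self.positions[:, 2],
                "yaw_deg": self.yaw_deg,
            }
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, **kw) -> "GroundTruthTrack":
        df = pd.read_csv(path)
        return cls(
            df["time_s"].to_numpy(),
            df[["x_m", "y_m", "z_m"]].to_numpy(),
            df["yaw_deg"].to_numpy(),
            **kw,
        )


def simulate_flight(
    profile: FlightProfile, seed: int = 0, scene: TunnelScene | None = None
) -> GroundTruthTrack:
    """Simulate a smooth tunnel passage, optionally with lateral scanning.

    The trajectory is a constant-speed advance along the tunnel axis plus a
    sinusoidal lateral oscillation (emulating the lateral scanning behaviour
    bees show in front of obstacles) and low-pass-filtered Gaussian jitter.
    Deterministic for a given (profile, seed).
    """
    if profile.speed <= 0:
        raise ValueError("mean forward speed must be positive")
    scene = scene or TunnelScene()
    rng = np.random.default_rng(seed)
    n = max(int(round(profile.duration * profile.sample_rate)) + 1, 2)
    t = np.arange(n) / profile.sample_rate
    start = profile.start or (0.05, 0.0, scene.flight_plane_z)
    x = start[0] + profile.speed * t
    phase = rng.uniform(0.0, 2.0 * math.pi) if profile.lateral_amplitude > 0 else 0.0
    y = start[1] + profile.lateral_amplitude * np.sin(
        2.0 * math.pi * profile.lateral_freq_hz * t + phase
    )
    z = np.full(n, start[2])
    if profile.noise_std > 0:
        # correlated jitter: white noise smoothed over ~60 ms
        sig = profile.noise_std
        win = max(profile.sample_rate * 0.06, 1.0)
        for arr in (x, y):
            raw = gaussian_filter1d(rng.standard_normal(n), win)
            rms = np.sqrt(np.mean(raw**2))
            arr += sig * raw / max(rms, 1e-12)
    # keep the path inside the tunnel walls
    half = scene.width / 2.0 - 0.01
    np.clip(y, -half, half, out=y)
    pos = np.column_stack([x, y, z])
    vel = np.gradient(pos, t, axis=0)
    yaw = np.degrees(np.arctan2(vel[:, 1], vel[:, 0]))
    return GroundTruthTrack(t, pos, yaw, profile.body_length, profile.body_width)


@dataclass
class FrameSequence:
    """An ordered stack of grayscale frames with camera metadata."""

    frames: np.ndarray  # (N, H, W) uint8
    camera: CameraModel

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (N, H, W) stack")

    @property
    def fps(self) -> float:
        return self.camera.fps

    @property
    def timestamps(self) -> np.ndarray:
        return np.arange(len(self.frames)) / self.fps

    def __len__(self) -> int:
        return len(self.frames)

    def save(self, directory) -> None:
        """Write frames as zero-padded numbered PNGs plus a camera YAML."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k, frame in enumerate(self.frames):
            iio.imwrite(directory / f"frame_{k:06d}.png", frame)
        self.camera.to_yaml(directory / "camera.yaml")

    @classmethod
    def load(cls, directory, camera: CameraModel | None = None) -> "FrameSequence":
        directory = Path(directory)
        paths = sorted(directory.glob("frame_*.png"))
        if not paths:
            raise FileNotFoundError(f"no frame_*.png files in {directory}")
        frames = np.stack([iio.imread(p) for p in paths])
        if frames.ndim == 4:  # RGB -> grayscale
            frames = frames[..., :3].mean(axis=-1).astype(np.uint8)
        if camera is None:
            camera = CameraModel.from_yaml(directory / "camera.yaml")
        return cls(frames, camera)


def _make_background(scene: TunnelScene, camera: CameraModel) -> np.ndarray:
    """Static floor + wall-texture bands (no barrier, no insect)."""
    w, h = camera.image_size
    frame = np.full((h, w), FLOOR_LEVEL, dtype=np.uint8)
    band = max(int(0.08 * h), 4)
    tex = scene.wall_texture
    tiled = np.tile(tex, (band // tex.shape[0] + 1, w // tex.shape[1] + 1))
    patch = np.where(tiled[:band, :w] > 0.5, TEXTURE_LIGHT, TEXTURE_DARK).astype(np.uint8)
    frame[:band] = patch
    frame[h - band :] = patch[::-1]
    return frame


def _draw_barrier(
    frame: np.ndarray, scene: TunnelScene, kin: BarrierKinematics, camera: CameraModel, t: float
) -> None:
    zp = scene.flight_plane_z
    xb = scene.barrier_plane_x
    gap_w, _ = gap_at_time(kin, t)
    u0, _ = camera.world_to_pixel((xb - BARRIER_THICKNESS_M / 2, 0.0, zp))
    u1, _ = camera.world_to_pixel((xb + BARRIER_THICKNESS_M / 2, 0.0, zp))
    h, w = frame.shape
    c0, c1 = int(round(min(u0, u1))), int(round(max(u0, u1)))
    if c1 < 0 or c0 >= w:
        return
    c0, c1 = max(c0, 0), min(c1, w - 1)
    # panel rows: from the tunnel walls inward to the gap edges
    ys = [scene.width / 2, gap_w / 2, -gap_w / 2, -scene.width / 2]
    vs = [camera.world_to_pixel((xb, y, zp))[1] for y in ys]
    v_wall_l, v_gap_l, v_gap_r, v_wall_r = (int(round(v)) for v in vs)
    top = slice(max(v_wall_l, 0), max(v_gap_l, 0))
    bot = slice(min(v_gap_r, h), min(v_wall_r, h))
    frame[top, c0 : c1 + 1] = PANEL_LEVEL
    frame[bot, c0 : c1 + 1] = PANEL_LEVEL


def _draw_insect(
    frame: np.ndarray,
    camera: CameraModel,
    pos: np.ndarray,
    yaw_deg: float,
    body_length: float,
    body_width: float,
    blur_sigma: float,
) -> None:
    h, w = frame.shape
    try:
        u, v = camera.world_to_pixel(pos)
    except ValueError:
        return
    s = camera.focal_px / (camera.position[2] - pos[2])
    a = body_length / 2.0 * s  # semi-major, px
    b = body_width / 2.0 * s
    # image-frame heading: v is down while world y is left -> negate yaw
    theta = math.radians(-yaw_deg)
    rad = int(math.ceil(a + 3 * blur_sigma + 2))
    r0, r1 = int(math.floor(v)) - rad, int(math.floor(v)) + rad + 1
    c0, c1 = int(math.floor(u)) - rad, int(math.floor(u)) + rad + 1
    if r1 <= 0 or c1 <= 0 or r0 >= h or c0 >= w:
        return
    rr0, cc0 = max(r0, 0), max(c0, 0)
    rr1, cc1 = min(r1, h), min(c1, w)
    rows = np.arange(rr0, rr1)[:, None] - v
    cols = np.arange(cc0, cc1)[None, :] - u
    ct, st = math.cos(theta), math.sin(theta)
    major = cols * ct + rows * st
    minor = -cols * st + rows * ct
    inside = (major / a) ** 2 + (minor / b) ** 2 <= 1.0
    patch = frame[rr0:rr1, cc0:cc1].astype(float)
    patch[inside] = INSECT_LEVEL
    if blur_sigma > 0:
        patch = gaussian_filter(patch, blur_sigma)
    frame[rr0:rr1, cc0:cc1] = np.clip(patch, 0, 255).astype(np.uint8)


def render_frame(
    scene: TunnelScene,
    kin: BarrierKinematics,
    camera: CameraModel,
    t: float,
    insect: tuple[np.ndarray, float] | None = None,
    body_length: float = 0.013,
    body_width: float = 0.004,
    blur_sigma: float = 1.0,
    background: np.ndarray | None = None,
) -> np.ndarray:
    """Render one frame at time ``t``; ``insect`` is (position, yaw_deg) or None."""
    frame = (_make_background(scene, camera) if background is None else background).copy()
    _draw_barrier(frame, scene, kin, camera, t)
    if insect is not None:
        pos, yaw = insect
        _draw_insect(frame, camera, np.asarray(pos, float), yaw, body_length, body_width, blur_sigma)
    return frame


def render_sequence(
    scene: TunnelScene,
    kin: BarrierKinematics,
    track: GroundTruthTrack,
    camera: CameraModel,
    n_frames: int | None = None,
    t0: float = 0.0,
    noise_std: float = 0.0,
    blur_sigma: float = 1.0,
    seed: int = 0,
) -> FrameSequence:
    """Render a frame sequence of the scene with the insect flying ``track``.

    Frame k is rendered at scene time ``t0 + k/fps`` with the insect at the
    track position interpolated at that time; frames before the track starts
    or after it ends simply lack the insect, as do frames where it is outside
    the camera's field of view.  ``noise_std`` adds per-pixel Gaussian noise.
    """
    if len(track.times) == 0:
        raise ValueError("empty track")
    fps = camera.fps
    if n_frames is None:
        n_frames = int(math.ceil((track.times[-1] - t0) * fps)) + 1
    bg = _make_background(scene, camera)
    rng = np.random.default_rng(seed)
    w, h = camera.image_size
    frames = np.empty((n_frames, h, w), dtype=np.uint8)
    for k in range(n_frames):
        t = t0 + k / fps
        insect = None
        if track.times[0] <= t <= track.times[-1]:
            pos, yaw = track.at(t)
            insect = (pos[0], yaw[0])
        frame = render_frame(
            scene, kin, camera, t, insect,
            track.body_length, track.body_width, blur_sigma, background=bg,
        )
        if noise_std > 0:
            noisy = frame.astype(np.float32)
            noisy += rng.normal(0.0, noise_std, size=frame.shape).astype(np.float32)
            frame = np.clip(noisy, 0, 255).astype(np.uint8)
        frames[k] = frame
    return FrameSequence(frames, camera)


def default_gap_roi(
    scene: TunnelScene, camera: CameraModel, inset_px: int = 1
) -> tuple[int, int, int, int]:
    """Pixel rectangle (x, y, w, h) covering the barrier band across the
    full tunnel width.

    With the default one-pixel inset the open-gap area is the only bright
    region inside the rectangle (gap-area calibration use).  A negative
    ``inset_px`` expands the rectangle instead, which is the form used to
    mask the moving barrier out of insect segmentation."""
    zp = scene.flight_plane_z
    xb = scene.barrier_plane_x
    u0, _ = camera.world_to_pixel((xb - BARRIER_THICKNESS_M / 2, 0.0, zp))
    u1, _ = camera.world_to_pixel((xb + BARRIER_THICKNESS_M / 2, 0.0, zp))
    _, v0 = camera.world_to_pixel((xb, scene.width / 2, zp))
    _, v1 = camera.world_to_pixel((xb, -scene.width / 2, zp))
    w_img, h_img = camera.image_size
    x = max(int(math.ceil(min(u0, u1))) + inset_px, 0)
    y = max(int(math.ceil(min(v0, v1))) + inset_px, 0)
    x2 = min(int(math.floor(max(u0, u1))) - inset_px, w_img)
    y2 = min(int(math.floor(max(v0, v1))) - inset_px, h_img)
    return x, y, x2 - x, y2 - y
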
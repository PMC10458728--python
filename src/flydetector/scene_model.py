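"""Tunnel world model: geometry, barrier kinematics, detectability distance.

The world frame is fixed throughout the package: ``x`` runs along the tunnel
axis from the entrance toward the exit, ``y`` is lateral (left-positive when
looking along +x), ``z`` is up, and the origin sits at the centre of the
entrance floor.  The barrier is a pair of vertical panels in the plane
``x = barrier_plane_x`` whose gap (measured along y, centred on the tunnel
axis) either stays fixed (static mode) or opens and closes as a constant-speed
triangle wave (dynamic mode).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "TunnelScene",
    "BarrierKinematics",
    "OmmatidialModel",
    "gap_linear_velocity",
    "obstacle_detection_distance",
    "tunnel_length_ok",
    "gap_at_time",
    "make_wall_texture",
    "load_scene",
    "save_scene",
]

#: Default tunnel dimensions in metres (length, width, height).
DEFAULT_TUNNEL_DIMS = (1.56, 0.28, 0.28)


def gap_linear_velocity(fp: float, rc: float, i: float = 64.0) -> float:
    """Linear opening speed of the barrier gap, v_c = 2*pi*f_p*r_c / i.

    Parameters
    ----------
    fp : float
        Stepper-motor pulse frequency in Hz (>= 0).
    rc : float
        Radius of the gear indexing circle in metres (> 0).
    i : float
        Reduction ratio of the stepper motor (> 0, default 64).

    Returns
    -------
    float
        Gap linear velocity in m/s.
    """
    if rc <= 0:
        raise ValueError(f"gear radius rc must be > 0, got {rc}")
    if i <= 0:
        raise ValueError(f"reduction ratio i must be > 0, got {i}")
    if fp < 0:
        raise ValueError(f"pulse frequency fp must be >= 0, got {fp}")
    return 2.0 * math.pi * fp * rc / i


def obstacle_detection_distance(d: float, delta_deg: float = 5.0) -> float:
    """Distance at which a gap of width ``d`` subtends one ommatidial angle.

    D = d / tan(delta/2): beyond this range the gap falls below the angular
    resolution of a single ommatidium (visual angle ``delta``, ~5 degrees for
    honeybees) and cannot be resolved.
    """
    if d <= 0:
        raise ValueError(f"gap width d must be > 0, got {d}")
    if not (0.0 < delta_deg < 180.0):
        raise ValueError(f"visual angle must be in (0, 180) degrees, got {delta_deg}")
    return d / math.tan(math.radians(delta_deg) / 2.0)


def tunnel_length_ok(length: float, d: float, delta_deg: float = 5.0) -> bool:
    """True when the tunnel is longer than twice the detection distance.

    This is the design constraint guaranteeing the insect can see the obstacle
    well before the midpoint of the tunnel.
    """
    return length > 2.0 * obstacle_detection_distance(d, delta_deg)


@dataclass
class OmmatidialModel:
    """Angular sampling of the compound eye (one ommatidium ~ 5 degrees)."""

    visual_angle_deg: float = 5.0

    def __post_init__(self) -> None:
        if not (0.0 < self.visual_angle_deg < 180.0):
            raise ValueError("visual_angle_deg must be in (0, 180)")

    def detection_distance(self, d: float) -> float:
        return obstacle_detection_distance(d, self.visual_angle_deg)


@dataclass
class BarrierKinematics:
    """Motion law of the barrier gap.

    In dynamic mode the gap width is a symmetric triangle wave between
    ``d_min`` and ``d_max`` whose slope magnitude is the gear-rack linear
    speed ``vc`` (from :func:`gap_linear_velocity`); the two panel edges move
    symmetrically about the tunnel axis, each at ``vc/2``.  In static mode the
    width is constant at ``d_min``.
    """

    mode: str = "dynamic"
    d_min: float = 0.02
    d_max: float = 0.10
    pulse_frequency: float = 64.0
    gear_radius: float = 0.01
    reduction_ratio: float = 64.0
    opening_at_t0: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("static", "dynamic"):
            raise ValueError(f"mode must be 'static' or 'dynamic', got {self.mode!r}")
        if not (0.0 <= self.d_min <= self.d_max):
            raise ValueError("require 0 <= d_min <= d_max")
        if self.mode == "dynamic" and self.d_min == self.d_max:
            raise ValueError("dynamic mode needs d_min < d_max")

    @property
    def vc(self) -> float:
        """Gap opening speed in m/s (slope of the width triangle wave)."""
        if self.mode == "static":
            return 0.0
        return gap_linear_velocity(
            self.pulse_frequency, self.gear_radius, self.reduction_ratio
        )

    @property
    def period(self) -> float:
        """Full open-close period of the triangle wave in seconds."""
        if self.mode == "static":
            return math.inf
        return 2.0 * (self.d_max - self.d_min) / self.vc

    @classmethod
    def static(cls, gap: float) -> "BarrierKinematics":
        """A barrier frozen at a constant gap width."""
        return cls(mode="static", d_min=gap, d_max=gap, pulse_frequency=0.0)


def gap_at_time(kin: BarrierKinematics, t: float) -> tuple[float, float]:
    """Gap width and signed opening rate at time ``t``.

    Returns
    -------
    (width, rate) : tuple of float
        ``width`` in metres, always within [d_min, d_max] and continuous in t;
        ``rate`` is d(width)/dt, alternating +-vc (0 in static mode).  Each
        panel edge moves at rate/2 since the gap is centred on the axis.
    """
    if t < 0:
        raise ValueError(f"time must be >= 0, got {t}")
    if kin.mode == "static" or kin.vc == 0.0:
        return kin.d_min, 0.0
    span = kin.d_max - kin.d_min
    # phase in [0, 2*span): first half opening, second half closing
    phase = (kin.vc * t) % (2.0 * span)
    if not kin.opening_at_t0:
        phase = (phase + span) % (2.0 * span)
    if phase < span:
        return kin.d_min + phase, kin.vc
    return kin.d_max - (phase - span), -kin.vc


def gap_edges_at_time(kin: BarrierKinematics, t: float) -> tuple[float, float]:
    """Lateral (y) positions of the two gap edges, (left, right) = (+w/2, -w/2)."""
    w, _ = gap_at_time(kin, t)
    return w / 2.0, -w / 2.0


def make_wall_texture(seed: int, size: tuple[int, int] = (256, 256)) -> np.ndarray:
    """Generate a two-level random wall pattern with a 1/f amplitude spectrum.

    White noise is filtered in the Fourier domain by 1/|f| and the result is
    binarised at its median, giving the red/white random pattern used on the
    tunnel walls (returned as a float array of {0, 1}; 1 = white).
    Deterministic for a given seed.
    """
    h, w = size
    if h < 8 or w < 8:
        raise ValueError("texture must be at least 8x8")
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((h, w))
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    f[0, 0] = 1.0  # keep DC finite; it is removed by the median split anyway
    spectrum = np.fft.fft2(noise) / f
    field_ = np.real(np.fft.ifft2(spectrum))
    return (field_ > np.median(field_)).astype(float)


def texture_spectral_slope(texture: np.ndarray) -> float:
    """Log-log slope of the radially averaged amplitude spectrum.

    Measured over the central decade of spatial frequencies; a 1/f pattern
    has slope close to -1.
    """
    h, w = texture.shape
    amp = np.abs(np.fft.fftshift(np.fft.fft2(texture - texture.mean())))
    cy, cx = h // 2, w // 2
    yy, xx = np.indices((h, w))
    r = np.hypot(yy - cy, xx - cx)
    rmax = min(cy, cx)
    # radial bins over the central decade [rmax/20, rmax/2]
    nbins = 24
    edges = np.logspace(np.log10(max(rmax / 20.0, 1.5)), np.log10(rmax / 2.0), nbins + 1)
    centers, means = [], []
    for lo, hi in zip(edges[:-1], edges[1:]):
        m = (r >= lo) & (r < hi)
        if m.any():
            centers.append(math.sqrt(lo * hi))
            means.append(amp[m].mean())
    lr = np.polyfit(np.log(centers), np.log(means), 1)
    return float(lr[0])


@dataclass
class TunnelScene:
    """The flight tunnel: a box with textured side walls and a barrier plane."""

    length: float = DEFAULT_TUNNEL_DIMS[0]
    width: float = DEFAULT_TUNNEL_DIMS[1]
    height: float = DEFAULT_TUNNEL_DIMS[2]
    barrier_plane_x: float = 1.26  # 0.30 m before the exit, as in the field rig
    texture_seed: int = 0
    wall_texture: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if min(self.length, self.width, self.height) <= 0:
            raise ValueError("tunnel dimensions must be positive")
        if not (0.0 < self.barrier_plane_x < self.length):
            raise ValueError("barrier plane must lie strictly inside the tunnel")
        if self.wall_texture is None:
            self.wall_texture = make_wall_texture(self.texture_seed)

    @property
    def flight_plane_z(self) -> float:
        """Mid-tunnel height, the assumed flight plane for 2D mapping."""
        return self.height / 2.0

    def contains(self, p) -> bool:
        x, y, z = np.asarray(p, dtype=float)
        return (
            0.0 <= x <= self.length
            and abs(y) <= self.width / 2.0
            and 0.0 <= z <= self.height
        )


def save_scene(scene: TunnelScene, kin: BarrierKinematics, path) -> None:
    """Write scene + kinematics to a YAML config (dimensions in metres)."""
    doc = {
        "tunnel": {
            "length": scene.length,
            "width": scene.width,
            "height": scene.height,
            "barrier_plane_x": scene.barrier_plane_x,
            "texture_seed": scene.texture_seed,
        },
        "barrier": {
            "mode": kin.mode,
            "d_min": kin.d_min,
            "d_max": kin.d_max,
            "pulse_frequency": kin.pulse_frequency,
            "gear_radius": kin.gear_radius,
            "reduction_ratio": kin.reduction_ratio,
            "opening_at_t0": kin.opening_at_t0,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_scene(path) -> tuple[TunnelScene, BarrierKinematics]:
    """Read a scene YAML written by :func:`save_scene`."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    scene = TunnelScene(**doc.get("tunnel", {}))
    kin = BarrierKinematics(**doc.get("barrier", {}))
    return scene, kin
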
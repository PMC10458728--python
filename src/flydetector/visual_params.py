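"""Reconstruction of the insect's visual input.

Two complementary views of "what the bee saw":

* **Geometric optic flow** — the angular velocity field over a spherical
  (ommatidial) grid of viewing directions, computed analytically by casting
  rays from the eye against the tunnel walls and the moving barrier panels.
  For a viewing direction d (unit vector, head frame), eye translation T,
  yaw rate omega and hit distance r on a surface moving at V_s, the motion
  field is

      flow(d) = -omega x d - (T_rel - (T_rel . d) d) / r,   T_rel = T - V_s

  projected onto the local azimuth (Vx) and elevation (Vy) unit vectors.
  Directions that exit the open tunnel ends keep only the rotational term.

* **Gap-geometry parameters** — with B the eye position and A, C the two gap
  edges, the retinal size gamma is the absolute wrapped difference of the
  edge bearings alpha and beta (atan2 form); gamma_dot is its time
  derivative (central differences) and RREV = gamma_dot / gamma, the
  relative retinal expansion velocity, whose small-angle head-on limit is
  the inverse time-to-contact v/D.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scene_model import BarrierKinematics, TunnelScene, gap_at_time

__all__ = [
    "EyeState",
    "FlowField",
    "VisualParamSeries",
    "cast_ray",
    "geometric_flow_field",
    "retinal_size",
    "retinal_size_rate",
    "rrev",
    "visual_param_series",
]

GAMMA_EPS = 1e-4  # rad; below this RREV is flagged undefined

SURFACES = ("none", "wall-left", "wall-right", "floor", "ceiling", "barrier-left", "barrier-right")


@dataclass
class EyeState:
    """Instantaneous eye pose and motion."""

    position: np.ndarray  # (3,), m
    velocity: np.ndarray  # (3,), m/s
    yaw_deg: float = 0.0
    yaw_rate_deg_s: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)
        if not np.all(np.isfinite(self.position)) or not np.all(np.isfinite(self.velocity)):
            raise ValueError("eye state must be finite")


def _ray_hits(
    scene: TunnelScene,
    kin: BarrierKinematics,
    origin: np.ndarray,
    dirs: np.ndarray,
    t: float,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized nearest-hit query for (N, 3) unit directions.

    Returns (r, surface index into SURFACES, surface velocity (N, 3)).
    """
    n = len(dirs)
    eps = 1e-9
    best_r = np.full(n, np.inf)
    best_s = np.zeros(n, dtype=int)  # 0 = none
    o = origin

    def consider(tt, cond, sid):
        m = (tt > eps) & cond & (tt < best_r)
        best_r[m] = tt[m]
        best_s[m] = sid

    with np.errstate(divide="ignore", invalid="ignore"):
        # side walls y = +W/2 (left) and y = -W/2 (right)
        for sid, yw in ((1, scene.width / 2), (2, -scene.width / 2)):
            tt = (yw - o[1]) / dirs[:, 1]
            p = o + tt[:, None] * dirs
            cond = (p[:, 0] >= 0) & (p[:, 0] <= scene.length) & (p[:, 2] >= 0) & (p[:, 2] <= scene.height)
            consider(tt, cond & np.isfinite(tt), sid)
        # floor z=0 and ceiling z=H
        for sid, zw in ((3, 0.0), (4, scene.height)):
            tt = (zw - o[2]) / dirs[:, 2]
            p = o + tt[:, None] * dirs
            cond = (p[:, 0] >= 0) & (p[:, 0] <= scene.length) & (np.abs(p[:, 1]) <= scene.width / 2)
            consider(tt, cond & np.isfinite(tt), sid)
        # barrier panels in the plane x = barrier_plane_x
        gap_w, rate = gap_at_time(kin, t)
        tt = (scene.barrier_plane_x - o[0]) / dirs[:, 0]
        p = o + tt[:, None] * dirs
        in_z = (p[:, 2] >= 0) & (p[:, 2] <= scene.height)
        left_panel = (p[:, 1] >= gap_w / 2) & (p[:, 1] <= scene.width / 2)
        right_panel = (p[:, 1] <= -gap_w / 2) & (p[:, 1] >= -scene.width / 2)
        fin = np.isfinite(tt)
        consider(tt, in_z & left_panel & fin, 5)
        consider(tt, in_z & right_panel & fin, 6)

    vel = np.zeros((n, 3))
    # each gap edge moves at half the opening rate: +rate/2 for the left
    # edge (y = +w/2), -rate/2 for the right edge
    vel[best_s == 5, 1] = rate / 2.0
    vel[best_s == 6, 1] = -rate / 2.0
    return best_r, best_s, vel


def cast_ray(
    scene: TunnelScene,
    kin: BarrierKinematics,
    origin,
    direction,
    t: float = 0.0,
) -> tuple[float, str, np.ndarray]:
    """Nearest intersection of a single ray with the tunnel and barrier.

    Returns (distance, surface name, surface velocity vector).  Rays that
    leave through the open tunnel ends return (inf, "none", 0).
    """
    origin = np.asarray(origin, dtype=float)
    direction = np.asarray(direction, dtype=float)
    nrm = np.linalg.norm(direction)
    if not math.isclose(nrm, 1.0, rel_tol=1e-6):
        raise ValueError("direction must be a unit vector")
    if not scene.contains(origin):
        raise ValueError(f"ray origin {origin} is outside the tunnel")
    r, s, v = _ray_hits(scene, kin, origin, direction[None, :], t)
    return float(r[0]), SURFACES[s[0]], v[0]


@dataclass
class FlowField:
    """Geometric optic flow sampled on an azimuth x elevation grid."""

    azimuth_deg: np.ndarray  # (N,)
    elevation_deg: np.ndarray  # (N,)
    vx: np.ndarray  # rad/s, horizontal (azimuthal) component
    vy: np.ndarray  # rad/s, vertical (elevational) component
    r: np.ndarray  # m, hit distance (inf where no hit)
    surface: np.ndarray  # (N,) str

    @property
    def magnitude(self) -> np.ndarray:
        return np.hypot(self.vx, self.vy)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "azimuth_deg": self.azimuth_deg,
                "elevation_deg": self.elevation_deg,
                "Vx_rad_s": self.vx,
                "Vy_rad_s": self.vy,
                "r_m": self.r,
                "surface": self.surface,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def _grid_directions(spacing_deg: float) -> tuple[np.ndarray, np.ndarray]:
    """Latitude-longitude grid (azimuth, elevation) in degrees, poles excluded."""
    az = np.arange(-180.0, 180.0, spacing_deg)
    el = np.arange(-90.0 + spacing_deg, 90.0, spacing_deg)
    azg, elg = np.meshgrid(az, el)
    return azg.ravel(), elg.ravel()


def geometric_flow_field(
    scene: TunnelScene,
    kin: BarrierKinematics,
    eye: EyeState,
    spacing_deg: float = 5.0,
) -> FlowField:
    """Geometric optic flow over the spherical ommatidial grid.

    Grid directions are expressed in the head frame (x forward along the
    yaw heading, y left, z up); the default 5-degree spacing matches the
    honeybee ommatidial visual angle.  Sign convention: Vx > 0 means the
    environment sweeps toward increasing azimuth (leftward in the head
    frame), Vy > 0 toward increasing elevation.
    """
    az_deg, el_deg = _grid_directions(spacing_deg)
    az = np.radians(az_deg)
    el = np.radians(el_deg)
    # head-frame viewing directions and local tangent basis
    d_head = np.column_stack(
        [np.cos(el) * np.cos(az), np.cos(el) * np.sin(az), np.sin(el)]
    )
    e_az = np.column_stack([-np.sin(az), np.cos(az), np.zeros_like(az)])
    e_el = np.column_stack(
        [-np.sin(el) * np.cos(az), -np.sin(el) * np.sin(az), np.cos(el)]
    )
    yaw = math.radians(eye.yaw_deg)
    c, s = math.cos(yaw), math.sin(yaw)
    R = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])  # head -> world

    d_world = d_head @ R.T
    r, sid, v_surf = _ray_hits(scene, kin, eye.position, d_world, eye.time)
    if np.any(r <= 0):
        raise ValueError("eye is touching a surface")

    # translational term, world frame -> head frame
    t_rel = eye.velocity[None, :] - v_surf  # (N, 3)
    radial = np.einsum("ij,ij->i", t_rel, d_world)
    trans_world = t_rel - radial[:, None] * d_world
    with np.errstate(divide="ignore", invalid="ignore"):
        trans_world = -trans_world / r[:, None]
    trans_world[~np.isfinite(r), :] = 0.0  # no hit: translational term vanishes
    trans_head = trans_world @ R

    omega = np.array([0.0, 0.0, math.radians(eye.yaw_rate_deg_s)])  # head frame (z up)
    rot_head = -np.cross(np.broadcast_to(omega, d_head.shape), d_head)

    flow = trans_head + rot_head
    vx = np.einsum("ij,ij->i", flow, e_az)
    vy = np.einsum("ij,ij->i", flow, e_el)
    return FlowField(
        az_deg, el_deg, vx, vy, r, np.array(SURFACES, dtype=object)[sid]
    )


def retinal_size(A, B, C) -> float:
    """Angular extent gamma (rad) of the gap [A, C] seen from the eye at B.

    alpha and beta are the atan2 bearings of C and A from B; gamma is the
    absolute wrapped difference, so the A/C labelling order cannot flip its
    sign.  Points are 2D (x, y) in the horizontal plane.
    """
    A = np.asarray(A, dtype=float)[:2]
    B = np.asarray(B, dtype=float)[:2]
    C = np.asarray(C, dtype=float)[:2]
    if np.allclose(A, B) or np.allclose(C, B):
        raise ValueError("eye position coincides with a gap edge")
    alpha = math.atan2(C[1] - B[1], C[0] - B[0])
    beta = math.atan2(A[1] - B[1], A[0] - B[0])
    diff = (alpha - beta + math.pi) % (2.0 * math.pi) - math.pi
    return abs(diff)


def retinal_size_rate(times, gamma) -> np.ndarray:
    """gamma_dot = d(gamma)/dt by central differences (one-sided at the ends)."""
    times = np.asarray(times, dtype=float)
    gamma = np.asarray(gamma, dtype=float)
    if len(times) < 3:
        raise ValueError("need at least 3 samples for a derivative series")
    return np.gradient(gamma, times)


def rrev(gamma, gamma_dot, gamma_eps: float = GAMMA_EPS):
    """Relative retinal expansion velocity RREV = gamma_dot / gamma (1/s).

    Where gamma < gamma_eps the ratio is undefined and flagged (NaN with
    defined=False) rather than clipped, preserving zero-crossing analyses.
    Scalar or array inputs.
    """
    gamma = np.asarray(gamma, dtype=float)
    gamma_dot = np.asarray(gamma_dot, dtype=float)
    defined = gamma >= gamma_eps
    out = np.full(gamma.shape, np.nan)
    np.divide(gamma_dot, gamma, out=out, where=defined)
    if out.ndim == 0:
        return float(out), bool(defined)
    return out, defined


@dataclass
class VisualParamSeries:
    """Time series of gap-geometry parameters along a flight."""

    time_s: np.ndarray
    gamma_rad: np.ndarray
    gamma_dot: np.ndarray
    rrev: np.ndarray
    defined: np.ndarray
    edge_a: np.ndarray  # (N, 2) world position of edge A (left, +y)
    edge_c: np.ndarray  # (N, 2) world position of edge C (right, -y)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.time_s,
                "gamma_rad": self.gamma_rad,
                "gamma_dot": self.gamma_dot,
                "rrev": self.rrev,
                "defined_flag": self.defined.astype(int),
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def visual_param_series(
    scene: TunnelScene,
    kin: BarrierKinematics,
    times,
    positions,
    gamma_eps: float = GAMMA_EPS,
) -> VisualParamSeries:
    """gamma, gamma_dot, RREV along a trajectory approaching the gap.

    ``positions`` is (N, 2) or (N, 3) world coordinates of the eye; the gap
    edges A (left, y = +w/2) and C (right, y = -w/2) sit in the barrier
    plane and move with the barrier kinematics.
    """
    times = np.asarray(times, dtype=float)
    pos = np.asarray(positions, dtype=float)[:, :2]
    if len(times) != len(pos):
        raise ValueError("times and positions must align")
    n = len(times)
    gam = np.empty(n)
    ea = np.empty((n, 2))
    ec = np.empty((n, 2))
    xb = scene.barrier_plane_x
    for k in range(n):
        w, _ = gap_at_time(kin, times[k])
        ea[k] = (xb, w / 2.0)
        ec[k] = (xb, -w / 2.0)
        gam[k] = retinal_size(ea[k], pos[k], ec[k])
    gdot = retinal_size_rate(times, gam)
    r, defined = rrev(gam, gdot, gamma_eps)
    return VisualParamSeries(times, gam, gdot, r, defined, ea, ec)
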
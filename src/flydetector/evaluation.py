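"""Simulated experiments: speed sweep, trajectory statistics, condition tests.

These reproduce, at desk scale, the rig's validation protocol: a
speed-adaptability sweep of the trigger (mock target crossing a 620 mm
detector field at 30 fps), an acquisition-accuracy harness over many
simulated single-bee passages, and dynamic-vs-static trajectory statistics
compared with paired t-tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scene_model import BarrierKinematics, TunnelScene
from .synthetic_imaging import (
    FlightProfile,
    detector_camera,
    render_sequence,
    simulate_flight,
)
from .trigger import (
    MedianBackgroundModel,
    TriggerConfig,
    TriggerState,
    extract_centroid,
    segment_foreground,
)
from .virtual_mapping import WorldTrack

__all__ = [
    "SweepResult",
    "TrajectoryStats",
    "run_speed_sweep",
    "simulate_passages",
    "mapping_experiment",
    "trajectory_stats",
    "compare_conditions",
]

FIELD_WIDTH_M = 0.62  # detector-camera footprint (620 mm monitor field)
DEFAULT_MISS_PROB = 0.02  # per-frame independent detection dropout


@dataclass
class SweepResult:
    """Trigger accuracy per target speed."""

    speeds: np.ndarray  # m/s
    trials: np.ndarray  # count per speed
    fires: np.ndarray  # crossings that fired exactly once
    accuracy: np.ndarray  # fires / trials

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "speed_m_s": self.speeds,
                "trials": self.trials,
                "fires": self.fires,
                "accuracy": self.accuracy,
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def max_speed_at(self, min_accuracy: float = 0.95) -> float:
        """Largest tested speed whose accuracy is at least ``min_accuracy``."""
        ok = self.accuracy >= min_accuracy
        if not ok.any():
            return float("nan")
        return float(self.speeds[ok].max())


def _run_one_crossing(
    scene: TunnelScene,
    kin: BarrierKinematics,
    camera,
    speed: float,
    rng: np.random.Generator,
    miss_prob: float,
    config: TriggerConfig,
    mock_size: tuple[float, float],
    lateral_amplitude: float = 0.0,
    reverse: bool = False,
) -> int:
    """Render one crossing of the detector field and count trigger fires."""
    fps = camera.fps
    # path spans the camera footprint plus margins so the target enters and
    # leaves the field within the sequence; random sub-frame start phase
    margin = 0.06
    x0 = scene.length / 2 - FIELD_WIDTH_M / 2 - margin
    x1 = scene.length / 2 + FIELD_WIDTH_M / 2 + margin
    duration = (x1 - x0) / speed
    profile = FlightProfile(
        speed=speed,
        duration=duration,
        start=(x0, 0.0, scene.flight_plane_z),
        lateral_amplitude=lateral_amplitude,
        sample_rate=max(fps * 4, 163.0),
        body_length=mock_size[0],
        body_width=mock_size[1],
    )
    track = simulate_flight(profile, seed=int(rng.integers(2**31)), scene=scene)
    if reverse:
        track.positions[:, 0] = x1 + x0 - track.positions[:, 0]
        track.yaw_deg = 180.0 - track.yaw_deg
    t0 = float(rng.uniform(0.0, 1.0 / fps))  # random frame phase
    n_frames = int(np.ceil(duration * fps)) + int(config.exit_patience) + 2
    seq = render_sequence(scene, kin, track, camera, n_frames=n_frames, t0=t0)
    model = MedianBackgroundModel().warmup(seq.frames[-1])  # last frame is empty
    state = TriggerState(config)
    fires = 0
    for frame in seq.frames:
        mask = segment_foreground(frame, model)
        try:
            centroid = extract_centroid(mask, config.area_limits)
        except Exception:
            centroid = None
        if centroid is not None and rng.uniform() < miss_prob:
            centroid = None  # camera dropout
        if state.push_detection(centroid) == "fire":
            fires += 1
    if state.finalize() == "fire":
        fires += 1
    return fires


def run_speed_sweep(
    speeds,
    n_trials: int = 20,
    n_reps: int = 3,
    fps: float = 30.0,
    miss_prob: float = DEFAULT_MISS_PROB,
    seed: int = 0,
    config: TriggerConfig | None = None,
) -> SweepResult:
    """Speed-adaptability sweep of the trigger.

    For each speed, ``n_trials * n_reps`` crossings of a mock target over the
    620 mm detector field are rendered at ``fps`` and fed through the full
    trigger pipeline with an independent per-frame miss probability; accuracy
    is the fraction of crossings that fire exactly once.
    """
    speeds = np.atleast_1d(np.asarray(speeds, dtype=float))
    if np.any(speeds <= 0):
        raise ValueError("speeds must be positive")
    config = config or TriggerConfig()
    scene = TunnelScene()
    kin = BarrierKinematics.static(0.06)
    camera = detector_camera(scene, fps=fps)
    rng = np.random.default_rng(seed)
    mock_size = (0.016, 0.006)  # high-contrast mock target, bee-like scale
    total = n_trials * n_reps
    fires_ok = np.zeros(len(speeds), dtype=int)
    for si, speed in enumerate(speeds):
        for _ in range(total):
            nf = _run_one_crossing(
                scene, kin, camera, speed, rng, miss_prob, config, mock_size
            )
            fires_ok[si] += int(nf == 1)
    trials = np.full(len(speeds), total)
    return SweepResult(speeds, trials, fires_ok, fires_ok / total)


def simulate_passages(
    n_passages: int = 100,
    speed_range: tuple[float, float] = (0.5, 2.0),
    lateral_amplitude: float = 0.02,
    miss_prob: float = DEFAULT_MISS_PROB,
    seed: int = 0,
    config: TriggerConfig | None = None,
) -> float:
    """Acquisition-accuracy harness: fraction of single-bee passages captured.

    Each passage is a rendered crossing in the configured direction at a
    forward speed drawn uniformly from ``speed_range`` with lateral scanning;
    a passage counts as captured when the trigger fires exactly once.
    """
    config = config or TriggerConfig()
    scene = TunnelScene()
    kin = BarrierKinematics.static(0.06)
    camera = detector_camera(scene)
    rng = np.random.default_rng(seed)
    ok = 0
    for _ in range(n_passages):
        speed = float(rng.uniform(*speed_range))
        nf = _run_one_crossing(
            scene, kin, camera, speed, rng, miss_prob, config,
            mock_size=(0.013, 0.004), lateral_amplitude=lateral_amplitude,
        )
        ok += int(nf == 1)
    return ok / n_passages


def mapping_experiment(seed: int = 0, noise_std: float = 2.0) -> dict:
    """Full mapping-fidelity experiment on one synthetic curved flight.

    Renders a 163 fps high-speed sequence of a curved flight at mid-tunnel
    height, extracts the pixel track, maps it onto the flight plane and
    measures two pixel-error statistics:

    * ``roundtrip_max`` — detected track vs. direct re-projection of the
      mapped world track (exact-inverse check; ~0 by construction);
    * ``virtual_max`` / ``virtual_mean`` — detected track vs. the track
      re-detected from a *re-render* of the virtual scene in which the
      insect model replays the mapped world trajectory.  This is the
      actual-vs-virtual trajectory comparison and carries the rasterization
      and detection error of the virtual pass.
    """
    from .pose_gap import TrackConfig, calibrate_gap_roi, track_pose
    from .synthetic_imaging import (
        GroundTruthTrack,
        default_gap_roi,
        highspeed_camera,
        render_frame,
    )
    from .virtual_mapping import CameraCalibration, map_track, roundtrip_error

    scene = TunnelScene()
    kin = BarrierKinematics()
    camera = highspeed_camera(scene)
    profile = FlightProfile(
        speed=0.35,
        duration=1.0,
        start=(1.06, 0.0, scene.flight_plane_z),
        lateral_amplitude=0.03,
        lateral_freq_hz=1.5,
        noise_std=0.002,
    )
    truth = simulate_flight(profile, seed=seed, scene=scene)
    seq = render_sequence(scene, kin, truth, camera, noise_std=noise_std, seed=seed)
    roi_rect = default_gap_roi(scene, camera)
    open_frame = render_frame(
        scene, BarrierKinematics.static(kin.d_max), camera, 0.0
    )
    gap_roi = calibrate_gap_roi(open_frame, roi_rect, kin.d_max)
    config = TrackConfig(
        background=render_frame(scene, kin, camera, 0.0),
        exclude_roi=default_gap_roi(scene, camera, inset_px=-3),
    )
    detected = track_pose(seq, config, gap_roi)
    cal = CameraCalibration(camera, scene.flight_plane_z)
    world = map_track(detected, cal)
    rt = roundtrip_error(detected, world, cal)

    # virtual pass: replay the mapped trajectory in the geometric scene,
    # re-render and re-detect, then compare pixel tracks point by point
    m = world.valid & np.isfinite(world.x_m)
    vt = GroundTruthTrack(
        world.time_s[m],
        np.column_stack([world.x_m[m], world.y_m[m], world.z_m[m]]),
        world.yaw_deg[m],
        truth.body_length,
        truth.body_width,
    )
    vseq = render_sequence(scene, kin, vt, camera, n_frames=len(seq), seed=seed + 1)
    redetected = track_pose(vseq, config)
    both = detected.valid & redetected.valid
    du = redetected.cx_px[both] - detected.cx_px[both]
    dv = redetected.cy_px[both] - detected.cy_px[both]
    err = np.hypot(du, dv)
    return {
        "roundtrip_max": rt["max"],
        "virtual_max": float(err.max()),
        "virtual_mean": float(err.mean()),
        "n_points": int(both.sum()),
    }


@dataclass
class TrajectoryStats:
    """Summary statistics of one flight trajectory."""

    flight_time: float  # s
    straightness: float  # net displacement / path length, in (0, 1]
    dispersion: float  # m, RMS lateral residual about the fitted line

    def as_dict(self) -> dict:
        return {
            "flight_time": self.flight_time,
            "straightness": self.straightness,
            "dispersion": self.dispersion,
        }


def trajectory_stats(world: WorldTrack) -> TrajectoryStats:
    """Flight time, straightness and lateral dispersion of a world track.

    Straightness is net displacement over path length; dispersion is the RMS
    perpendicular residual about the least-squares line through the planar
    (x, y) path.  Both are invariant to rigid motions of the track.
    """
    m = world.valid & np.isfinite(world.x_m) & np.isfinite(world.y_m)
    if m.sum() < 2:
        raise ValueError("need at least 2 valid samples")
    t = world.time_s[m]
    p = np.column_stack([world.x_m[m], world.y_m[m]])
    flight_time = float(t[-1] - t[0])
    seg = np.diff(p, axis=0)
    path_len = float(np.sum(np.hypot(seg[:, 0], seg[:, 1])))
    net = float(np.hypot(*(p[-1] - p[0])))
    straightness = net / path_len if path_len > 0 else 1.0
    # principal line through the path; dispersion = RMS perpendicular residual
    centered = p - p.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    normal = vt[1]
    dispersion = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return TrajectoryStats(flight_time, straightness, dispersion)


def compare_conditions(
    group_a: list[TrajectoryStats],
    group_b: list[TrajectoryStats],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Paired t-tests between two groups of trajectory statistics.

    One row per statistic (flight_time, straightness, dispersion) with the
    paired t statistic, two-sided p value and a significance flag at
    ``alpha``.  Unequal group sizes fall back to an unpaired (Welch) test
    with a warning column.
    """
    if len(group_a) < 3 or len(group_b) < 3:
        raise ValueError("need at least 3 trajectories per group")
    paired = len(group_a) == len(group_b)
    rows = []
    for key in ("flight_time", "straightness", "dispersion"):
        a = np.array([s.as_dict()[key] for s in group_a])
        b = np.array([s.as_dict()[key] for s in group_b])
        if paired:
            if np.allclose(a, b):
                tstat, p = 0.0, 1.0  # degenerate: identical groups
            else:
                tstat, p = stats.ttest_rel(a, b)
        else:
            tstat, p = stats.ttest_ind(a, b, equal_var=False)
        rows.append(
            {
                "statistic": key,
                "mean_a": a.mean(),
                "mean_b": b.mean(),
                "t": float(tstat),
                "p": float(p),
                "significant": bool(p < alpha),
                "test": "paired" if paired else "welch-unpaired",
            }
        )
    return pd.DataFrame(rows)
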
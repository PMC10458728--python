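import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import flydetector as fd
from flydetector.pose_gap import TrackConfig, calibrate_gap_roi, track_pose
from flydetector.synthetic_imaging import default_gap_roi, render_frame

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scene():
    return fd.TunnelScene()


@pytest.fixture(scope="session")
def kin_dynamic():
    return fd.BarrierKinematics()


@pytest.fixture(scope="session")
def kin_static():
    return fd.BarrierKinematics.static(0.06)


@pytest.fixture(scope="session")
def hs_camera(scene):
    return fd.highspeed_camera(scene)


@pytest.fixture(scope="session")
def crossing(scene, kin_dynamic, hs_camera):
    """A noiseless high-speed render of a curved flight through the gap
    region, with everything needed to test the extraction pipeline."""
    profile = fd.FlightProfile(
        speed=0.35,
        duration=1.0,
        start=(1.06, 0.0, scene.flight_plane_z),
        lateral_amplitude=0.03,
        lateral_freq_hz=1.5,
    )
    track = fd.simulate_flight(profile, seed=3, scene=scene)
    seq = fd.render_sequence(scene, kin_dynamic, track, hs_camera, seed=1)
    roi_rect = default_gap_roi(scene, hs_camera)
    open_frame = render_frame(
        scene, fd.BarrierKinematics.static(kin_dynamic.d_max), hs_camera, 0.0
    )
    gap_roi = calibrate_gap_roi(open_frame, roi_rect, kin_dynamic.d_max)
    config = TrackConfig(
        background=render_frame(scene, kin_dynamic, hs_camera, 0.0),
        exclude_roi=default_gap_roi(scene, hs_camera, inset_px=-3),
    )
    return {
        "track": track,
        "seq": seq,
        "gap_roi": gap_roi,
        "config": config,
        "camera": hs_camera,
    }


@pytest.fixture(scope="session")
def pose_track(crossing):
    return track_pose(crossing["seq"], crossing["config"], crossing["gap_roi"])
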
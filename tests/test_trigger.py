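import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import flydetector as fd
from flydetector.evaluation import _run_one_crossing
from flydetector.trigger import (
    AmbiguousDetection,
    MedianBackgroundModel,
    TriggerConfig,
    TriggerState,
    direction_statistic,
    extract_centroid,
    run_trigger,
    segment_foreground,
)


def _flat_frame(shape=(120, 200), level=200):
    return np.full(shape, level, dtype=np.uint8)


def _with_ellipse(frame, cx, cy, a=10, b=6, level=30):
    out = frame.copy()
    yy, xx = np.indices(frame.shape)
    out[((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0] = level
    return out


class TestSegmentation:
    def test_background_frame_is_empty(self):
        rng = np.random.default_rng(0)
        warm = [np.clip(_flat_frame() + rng.normal(0, 2, (120, 200)), 0, 255).astype(np.uint8) for _ in range(5)]
        model = MedianBackgroundModel().warmup(warm)
        probe = np.clip(_flat_frame() + rng.normal(0, 2, (120, 200)), 0, 255).astype(np.uint8)
        mask = segment_foreground(probe, model)
        assert mask.mean() < 0.005

    def test_dark_blob_area(self):
        model = MedianBackgroundModel().warmup(_flat_frame())
        frame = _with_ellipse(_flat_frame(), 100, 60, a=9, b=7)
        true_area = (((np.indices((120, 200))[1] - 100) / 9) ** 2 + ((np.indices((120, 200))[0] - 60) / 7) ** 2 <= 1).sum()
        mask = segment_foreground(frame, model)
        assert mask.sum() == pytest.approx(true_area, rel=0.25)

    def test_mask_stability(self):
        model = MedianBackgroundModel().warmup(_flat_frame())
        rng = np.random.default_rng(1)
        f = _with_ellipse(_flat_frame(), 100, 60)
        masks = []
        for _ in range(2):
            noisy = np.clip(f + rng.normal(0, 2, f.shape), 0, 255).astype(np.uint8)
            masks.append(segment_foreground(noisy, model).astype(bool))
        inter = (masks[0] & masks[1]).sum()
        union = (masks[0] | masks[1]).sum()
        assert inter / union > 0.8

    def test_shape_mismatch(self):
        model = MedianBackgroundModel().warmup(_flat_frame())
        with pytest.raises(ValueError):
            segment_foreground(np.zeros((10, 10)), model)


class TestExtractCentroid:
    def test_empty_mask(self):
        assert extract_centroid(np.zeros((50, 50))) is None

    def test_rectangle_centroid(self):
        mask = np.zeros((100, 100))
        mask[40:50, 30:50] = 1  # 20 wide x 10 tall, top-left (30, 40)
        assert extract_centroid(mask, (50, 5000)) == pytest.approx((39.5, 44.5))

    def test_two_blobs_ambiguous(self):
        mask = np.zeros((100, 200))
        mask[10:30, 10:30] = 1
        mask[60:80, 150:170] = 1
        with pytest.raises(AmbiguousDetection):
            extract_centroid(mask, (50, 5000))

    def test_area_filter(self):
        mask = np.zeros((100, 100))
        mask[10:12, 10:12] = 1  # 4 px, below min area
        assert extract_centroid(mask, (50, 5000)) is None


class TestDirectionStatistic:
    @pytest.mark.parametrize(
        "queue,expected",
        [
            ([50, 50, 50, 50, 50], 0.0),
            ([0, 2, 4, 6, 8], 1.6),
            ([8, 6, 4, 2, 0], -1.6),
        ],
    )
    def test_examples(self, queue, expected):
        assert direction_statistic(queue) == pytest.approx(expected)

    def test_partial_queue_rejected(self):
        with pytest.raises(ValueError):
            direction_statistic([5.0])

    @given(st.lists(st.floats(min_value=-1e4, max_value=1e4), min_size=2, max_size=20))
    def test_telescoping_identity(self, queue):
        """The mean of consecutive differences telescopes to (last-first)/n."""
        explicit = sum(b - a for a, b in zip(queue, queue[1:])) / len(queue)
        assert direction_statistic(queue) == pytest.approx(explicit, abs=1e-9)


def _feed(state, xs, gap_after=5):
    fired = 0
    for x in xs:
        if state.push_detection((x, 50.0) if x is not None else None) == "fire":
            fired += 1
    for _ in range(gap_after):
        if state.push_detection(None) == "fire":
            fired += 1
    return fired


class TestTriggerLogic:
    def test_forward_crossing_fires_once(self):
        state = TriggerState(TriggerConfig(direction="+x"))
        assert _feed(state, list(range(10, 190, 12))) == 1

    def test_wrong_direction_silent(self):
        state = TriggerState(TriggerConfig(direction="-x"))
        assert _feed(state, list(range(10, 190, 12))) == 0

    def test_retreat_does_not_fire(self):
        xs = list(range(10, 100, 10)) + list(range(100, 5, -10))
        for direction in ("+x", "-x"):
            state = TriggerState(TriggerConfig(direction=direction))
            assert _feed(state, xs) == 0

    def test_short_crossing_fires(self):
        """Two detection frames suffice (fast target, queue never fills)."""
        state = TriggerState(TriggerConfig(direction="+x", queue_len=5))
        assert _feed(state, [40, 160]) == 1

    def test_single_detection_cannot_fire(self):
        state = TriggerState(TriggerConfig(direction="+x"))
        assert _feed(state, [100]) == 0

    def test_two_successive_crossings(self):
        state = TriggerState(TriggerConfig(direction="+x"))
        n = _feed(state, list(range(10, 190, 12)))
        n += _feed(state, list(range(10, 190, 12)))
        assert n == 2


@pytest.fixture(scope="module")
def rendered(scene, kin_static):
    camera = fd.detector_camera(scene)
    profile = fd.FlightProfile(
        speed=1.0, duration=0.74, start=(0.41, 0.0, scene.flight_plane_z),
        body_length=0.016, body_width=0.006,
    )
    track = fd.simulate_flight(profile, seed=5, scene=scene)
    seq = fd.render_sequence(scene, kin_static, track, camera, n_frames=28)
    model = MedianBackgroundModel().warmup(seq.frames[-1])
    return seq, model


class TestRenderedCrossing:
    def test_fires_once_on_correct_direction(self, rendered):
        seq, model = rendered
        events = run_trigger(seq.frames, model, TriggerConfig(direction="+x"))
        assert len(events) == 1
        assert events[0].n_detection_frames >= 2
        assert events[0].mean_pxs > 0

    def test_direction_gate(self, rendered):
        seq, model = rendered
        assert run_trigger(seq.frames, model, TriggerConfig(direction="-x")) == []

    def test_mirror_symmetry(self, rendered):
        """Flipping frames horizontally swaps the firing direction."""
        seq, model = rendered
        flipped = seq.frames[:, :, ::-1]
        fmodel = MedianBackgroundModel().warmup(flipped[-1])
        assert len(run_trigger(flipped, fmodel, TriggerConfig(direction="-x"))) == 1
        assert run_trigger(flipped, fmodel, TriggerConfig(direction="+x")) == []


class TestSpeedLimits:
    def test_noiseless_trigger_rate_at_moderate_speed(self, scene, kin_static):
        camera = fd.detector_camera(scene)
        rng = np.random.default_rng(0)
        cfg = TriggerConfig()
        for speed in (2.0, 8.0):
            fires = [
                _run_one_crossing(scene, kin_static, camera, speed, rng, 0.0, cfg, (0.016, 0.006))
                for _ in range(5)
            ]
            assert fires == [1] * 5, f"speed {speed}"

    def test_too_fast_cannot_fire(self, scene, kin_static):
        """Above ~9.3 m/s fewer than 2 detection frames exist at 30 fps."""
        camera = fd.detector_camera(scene)
        rng = np.random.default_rng(0)
        cfg = TriggerConfig()
        fires = [
            _run_one_crossing(scene, kin_static, camera, 20.0, rng, 0.0, cfg, (0.016, 0.006))
            for _ in range(5)
        ]
        assert sum(fires) == 0
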
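"""Segmentation, detection, ROI tracking, and kinematics estimation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from microswim.imaging import ImagingConfig, render_frame
from microswim.sim import AgentState, MotilityParams
from microswim.tracking import (
    Detection,
    RoiTrackerParams,
    SegmentationParams,
    SelectionError,
    ShapeFilterParams,
    Track,
    detect_cells,
    estimate_kinematics,
    segment_green,
    track_single,
)


def brute_force_mask(frame: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Per-pixel python evaluation of the green predicate (oracle)."""
    h, w, _ = frame.shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            rr, gg, bb = (int(v) for v in frame[r, c])
            out[r, c] = gg >= params.green_abs_min and gg - max(rr, bb) >= params.green_margin
    return out


class TestSegmentGreen:
    def test_black_frame_empty_mask(self):
        frame = np.zeros((8, 8, 3), dtype=np.uint8)
        assert segment_green(frame).sum() == 0

    def test_pure_green_full_mask(self):
        frame = np.zeros((8, 8, 3), dtype=np.uint8)
        frame[..., 1] = 255
        assert segment_green(frame).all()

    def test_grayscale_rejected(self):
        with pytest.raises(ValueError, match="RGB"):
            segment_green(np.zeros((8, 8), dtype=np.uint8))

    def test_rendered_ellipse_matches_brute_force(self):
        cfg = ImagingConfig(frame_size=(80, 60), fov_origin_um=(-80.0, 60.0))
        frame = render_frame([AgentState((0.0, 0.0), 0.5, MotilityParams())], cfg)
        params = SegmentationParams()
        np.testing.assert_array_equal(segment_green(frame, params), brute_force_mask(frame, params))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        data=st.integers(0, 2**32 - 1),
        abs_min=st.integers(0, 255),
        margin=st.integers(0, 255),
    )
    def test_random_frames_match_brute_force(self, data, abs_min, margin):
        gen = np.random.default_rng(data)
        frame = gen.integers(0, 256, size=(6, 7, 3), dtype=np.uint8)
        params = SegmentationParams(abs_min, margin)
        np.testing.assert_array_equal(segment_green(frame, params), brute_force_mask(frame, params))

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**32 - 1), m1=st.integers(0, 120), m2=st.integers(0, 120))
    def test_mask_monotone_in_green_margin(self, seed, m1, m2):
        """Raising green_margin never grows the mask."""
        gen = np.random.default_rng(seed)
        frame = gen.integers(0, 256, size=(12, 12, 3), dtype=np.uint8)
        lo, hi = sorted((m1, m2))
        mask_lo = segment_green(frame, SegmentationParams(green_margin=lo))
        mask_hi = segment_green(frame, SegmentationParams(green_margin=hi))
        assert mask_hi.sum() <= mask_lo.sum()
        assert not np.any(mask_hi & ~mask_lo)


def oracle_moments(mask: np.ndarray):
    """Independent centroid/axes/orientation from raw pixel coordinates.

    Covariance eigendecomposition with the 1/12 per-pixel variance term;
    full axes are 4√λ (exact for a filled ellipse); image angle from the
    leading eigenvector.
    """
    rows, cols = np.nonzero(mask)
    cx, cy = cols.mean(), rows.mean()
    x = cols - cx
    y = rows - cy
    cov = np.array([[np.mean(x * x) + 1 / 12, np.mean(x * y)],
                    [np.mean(x * y), np.mean(y * y) + 1 / 12]])
    vals, vecs = np.linalg.eigh(cov)
    major, minor = 4 * math.sqrt(vals[1]), 4 * math.sqrt(vals[0])
    vx, vy = vecs[:, 1]
    angle_img = math.atan2(vy, vx)
    return (cx, cy), major, minor, angle_img % math.pi


class TestDetectCells:
    def test_empty_mask(self):
        assert detect_cells(np.zeros((10, 10), dtype=bool), 2.0) == []

    def test_rendered_ellipse_against_oracle(self):
        """One 60×10 μm cell: centroid within 1 px, aspect ≈ 6 within 15%."""
        cfg = ImagingConfig(frame_size=(100, 100), fov_origin_um=(-100.0, 100.0))
        agent = AgentState((0.0, 0.0), 0.4, MotilityParams())
        frame = render_frame([agent], cfg, sizes_um=np.array([[60.0, 10.0]]))
        mask = segment_green(frame)
        dets = detect_cells(mask, cfg.pixel_scale_um)
        assert len(dets) == 1
        det = dets[0]
        (ocx, ocy), omaj, omin, oang = oracle_moments(mask)
        assert det.centroid_px[0] == pytest.approx(ocx, abs=1e-9)
        assert det.centroid_px[1] == pytest.approx(ocy, abs=1e-9)
        assert det.major_um == pytest.approx(omaj * cfg.pixel_scale_um, rel=1e-9)
        assert det.minor_um == pytest.approx(omin * cfg.pixel_scale_um, rel=1e-9)
        # against ground truth
        gx, gy = 99 / 2, 99 / 2
        assert math.hypot(det.centroid_px[0] - gx, det.centroid_px[1] - gy) <= 1.0
        assert det.aspect == pytest.approx(6.0, rel=0.15)
        # chamber-frame axis: heading 0.4 → axis angle 0.4 (mod π)
        assert det.orientation == pytest.approx(0.4, abs=0.05)

    def test_round_blob_rejected_by_aspect(self):
        """A circular component of valid area fails the elongation gate."""
        mask = np.zeros((60, 60), dtype=bool)
        rr, cc = np.ogrid[:60, :60]
        mask[(rr - 30) ** 2 + (cc - 30) ** 2 <= 10**2] = True  # area ~314 px = 1256 μm²
        assert detect_cells(mask, 2.0) == []
        relaxed = ShapeFilterParams(area_range_um2=(100.0, 2000.0), aspect_min=1.0)
        assert len(detect_cells(mask, 2.0, relaxed)) == 1

    def test_too_small_and_too_large_rejected(self):
        mask = np.zeros((50, 200), dtype=bool)
        mask[10:12, 10:16] = True  # 12 px → 48 μm², below range
        mask[20:40, 20:190] = True  # 3400 px → 13600 μm², above range
        assert detect_cells(mask, 2.0) == []

    def test_sorted_by_area_descending(self):
        cfg = ImagingConfig(frame_size=(200, 100), fov_origin_um=(-200.0, 100.0))
        agents = [
            AgentState((-100.0, 0.0), 0.0, MotilityParams()),
            AgentState((100.0, 0.0), 0.0, MotilityParams()),
        ]
        sizes = np.array([[50.0, 8.0], [80.0, 15.0]])
        frame = render_frame(agents, cfg, sizes_um=sizes)
        dets = detect_cells(segment_green(frame), cfg.pixel_scale_um)
        assert len(dets) == 2
        assert dets[0].area_px >= dets[1].area_px


def _det(x, y, frame=0, area=100):
    return Detection(frame, (x, y), area, area * 4.0, 60.0, 10.0, 0.0)


class TestTrackSingle:
    def test_follows_single_detection(self):
        dets = [[_det(10.0 + f, 20.0)] for f in range(10)]
        tr = track_single(dets, (10.0, 20.0))
        assert len(tr) == 10
        np.testing.assert_allclose(tr.centroid_px[:, 0], 10.0 + np.arange(10))
        assert tr.status == "active"

    def test_no_detection_in_roi_raises(self):
        dets = [[_det(200.0, 200.0)]]
        with pytest.raises(SelectionError):
            track_single(dets, (10.0, 10.0), params=RoiTrackerParams(roi_radius_px=40))

    def test_matches_brute_force_nearest_neighbor(self):
        """Two moving detections per frame: choice equals exhaustive argmin."""
        gen = np.random.default_rng(8)
        n_frames = 30
        pa = np.cumsum(gen.normal(0, 3, size=(n_frames, 2)), axis=0) + [100, 100]
        pb = np.cumsum(gen.normal(0, 3, size=(n_frames, 2)), axis=0) + [140, 100]
        dets = [[_det(*pa[f]), _det(*pb[f])] for f in range(n_frames)]
        tr = track_single(dets, tuple(pa[0]), params=RoiTrackerParams(roi_radius_px=60))
        # oracle: greedy exhaustive nearest-neighbor from the same seed point
        expect = []
        last = tuple(pa[0])
        for f in range(n_frames):
            cands = [tuple(pa[f]), tuple(pb[f])]
            d = [math.hypot(c[0] - last[0], c[1] - last[1]) for c in cands]
            if f == 0:
                chosen = cands[int(np.argmin(d))]
            else:
                within = [i for i, dd in enumerate(d) if dd <= 60]
                chosen = cands[min(within, key=lambda i: d[i])]
            expect.append(chosen)
            last = chosen
        np.testing.assert_allclose(tr.centroid_px, np.array(expect))

    def test_tie_break_prefers_larger_area(self):
        dets = [[_det(10.0, 0.0, area=50), _det(-10.0, 0.0, area=80)]]
        tr = track_single(dets, (0.0, 0.0))
        assert tr.centroid_px[0, 0] == -10.0

    def test_lost_after_max_missed_frames(self):
        """Detections vanish for max_missed + 1 frames → track ends lost."""
        params = RoiTrackerParams(max_missed_frames=3)
        dets = [[_det(10.0, 10.0)]] * 5 + [[]] * 4 + [[_det(10.0, 10.0)]] * 3
        tr = track_single(dets, (10.0, 10.0), params=params)
        assert tr.status == "lost"
        assert tr.frame_indices[-1] == 4

    def test_survives_short_gap(self):
        params = RoiTrackerParams(max_missed_frames=3)
        dets = [[_det(10.0, 10.0)]] * 5 + [[]] * 3 + [[_det(10.0, 10.0)]] * 3
        tr = track_single(dets, (10.0, 10.0), params=params)
        assert tr.status == "active"
        assert len(tr) == 8


def _make_track(centroids_px, frames=None):
    centroids_px = np.asarray(centroids_px, dtype=float)
    n = len(centroids_px)
    return Track(
        track_id=0,
        frame_indices=np.arange(n) if frames is None else frames,
        centroid_px=centroids_px,
        orientation=np.zeros(n),
        area_um2=np.full(n, 500.0),
        aspect=np.full(n, 5.0),
    )


class TestEstimateKinematics:
    def test_stationary_track_zero_speed(self):
        tr = _make_track(np.tile([50.0, 60.0], (10, 1)))
        estimate_kinematics(tr, fps=10.0, pixel_scale_um=2.0)
        np.testing.assert_allclose(tr.speed_um_s, 0.0, atol=1e-12)

    def test_straight_line_speed(self):
        """1 px/frame at 2 μm/px and 10 fps → 20 μm/s at interior samples."""
        pts = np.column_stack([np.arange(20.0), np.zeros(20)])
        tr = _make_track(pts)
        estimate_kinematics(tr, fps=10.0, pixel_scale_um=2.0)
        np.testing.assert_allclose(tr.speed_um_s, 20.0, rtol=1e-12)
        # rightward motion in image = rightward in chamber (+x)
        np.testing.assert_allclose(tr.motion_direction[1:-1], 0.0, atol=1e-12)

    def test_image_y_down_maps_to_chamber_y_up(self):
        pts = np.column_stack([np.zeros(10), np.arange(10.0)])  # moving down-screen
        tr = _make_track(pts)
        estimate_kinematics(tr, fps=10.0, pixel_scale_um=2.0)
        np.testing.assert_allclose(tr.motion_direction[2:-2], -np.pi / 2, atol=1e-9)

    def test_circular_track_speed(self):
        """Circle radius R, angular rate ω → speed ≈ ωR (window ≪ period)."""
        R_px, omega, fps = 50.0, 0.4, 25.0
        t = np.arange(300) / fps
        pts = np.column_stack([200 + R_px * np.cos(omega * t), 200 + R_px * np.sin(omega * t)])
        tr = _make_track(pts)
        estimate_kinematics(tr, fps=fps, pixel_scale_um=2.0, window=5)
        expected = omega * R_px * 2.0  # μm/s
        mid = tr.speed_um_s[20:-20]
        assert np.abs(mid - expected).max() / expected < 0.02

    def test_short_track_rejected(self):
        tr = _make_track(np.zeros((3, 2)))
        with pytest.raises(ValueError, match="shorter than"):
            estimate_kinematics(tr, 10.0, 2.0, window=5)

    def test_body_orientation_resolved_toward_motion(self):
        """Moving leftward with axis 0 (mod π): resolved orientation ≈ π."""
        pts = np.column_stack([100.0 - 2 * np.arange(15.0), np.zeros(15)])
        tr = _make_track(pts)
        tr.orientation = np.zeros(15)  # axis along x
        estimate_kinematics(tr, fps=10.0, pixel_scale_um=2.0)
        assert np.allclose(np.abs(tr.body_orientation[2:-2]), np.pi, atol=1e-9)

    def test_determinism(self):
        gen = np.random.default_rng(3)
        pts = np.cumsum(gen.normal(0, 2, size=(30, 2)), axis=0) + 100
        t1 = _make_track(pts.copy())
        t2 = _make_track(pts.copy())
        estimate_kinematics(t1, 10.0, 2.0)
        estimate_kinematics(t2, 10.0, 2.0)
        np.testing.assert_array_equal(t1.speed_um_s, t2.speed_um_s)
        np.testing.assert_array_equal(t1.motion_direction, t2.motion_direction)
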
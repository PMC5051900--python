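"""Green-channel segmentation, contour/shape filtering, and ROI tracking.

The recognition pipeline isolates cells by filtering for green pixel values,
extracts connected components, keeps components whose size and shape are
consistent with an elongated ~50–80 μm cell, and follows a selected cell
with a nearest-neighbor region-of-interest tracker.  Orientation comes from
image second moments; velocity from (smoothed) changes in position.

Image coordinates are (col, row) with the origin top-left and rows growing
downward; all exported kinematics are converted to the chamber frame
(y up), so ``motion_direction`` of a cell moving toward the top of the
image is +π/2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from skimage import measure

from microswim.sim import wrap_angle

__all__ = [
    "SegmentationParams",
    "ShapeFilterParams",
    "RoiTrackerParams",
    "Detection",
    "Track",
    "SelectionError",
    "segment_green",
    "detect_cells",
    "track_single",
    "estimate_kinematics",
    "track_video",
]


class SelectionError(ValueError):
    """Raised when no detection lies within the ROI at the seed frame."""


@dataclass(frozen=True)
class SegmentationParams:
    """Green-pixel predicate: G ≥ green_abs_min AND G − max(R, B) ≥ green_margin."""

    green_abs_min: int = 60
    green_margin: int = 20

    def __post_init__(self) -> None:
        for name in ("green_abs_min", "green_margin"):
            v = getattr(self, name)
            if not 0 <= v <= 255:
                raise ValueError(f"{name} must be in [0, 255], got {v}")


@dataclass(frozen=True)
class ShapeFilterParams:
    """Size/shape gate for candidate cells.

    ``area_range_um2`` bounds the component area; ``aspect_min`` (major/minor
    of the moment ellipse) enforces the elongated cell shape.
    """

    area_range_um2: tuple[float, float] = (0.0, 0.0)  # filled by from_cell_size
    aspect_min: float = 1.5

    def __post_init__(self) -> None:
        if self.area_range_um2 == (0.0, 0.0):
            object.__setattr__(
                self, "area_range_um2", type(self).from_cell_size().area_range_um2
            )
        lo, hi = self.area_range_um2
        if not (0 < lo <= hi):
            raise ValueError("area_range_um2 must be positive and ordered")
        if self.aspect_min < 1:
            raise ValueError("aspect_min must be ≥ 1")

    @classmethod
    def from_cell_size(
        cls,
        length_range_um: tuple[float, float] = (50.0, 80.0),
        width_range_um: tuple[float, float] = (8.0, 15.0),
        pad: float = 0.3,
        aspect_min: float = 1.5,
    ) -> "ShapeFilterParams":
        """Derive area bounds from body size ranges, padded by ±``pad``.

        A cell is modeled as a filled ellipse, area = (π/4)·length·width.
        """
        lo = math.pi / 4 * length_range_um[0] * (1 - pad) * width_range_um[0] * (1 - pad)
        hi = math.pi / 4 * length_range_um[1] * (1 + pad) * width_range_um[1] * (1 + pad)
        return cls(area_range_um2=(lo, hi), aspect_min=aspect_min)


@dataclass(frozen=True)
class RoiTrackerParams:
    roi_radius_px: float = 40.0
    max_missed_frames: int = 5
    smoothing_window: int = 5

    def __post_init__(self) -> None:
        if self.roi_radius_px <= 0:
            raise ValueError("roi_radius_px must be positive")
        if self.smoothing_window < 3 or self.smoothing_window % 2 == 0:
            raise ValueError("smoothing_window must be odd and ≥ 3")
        if self.max_missed_frames < 0:
            raise ValueError("max_missed_frames must be ≥ 0")


@dataclass
class Detection:
    """One segmented candidate cell in one frame."""

    frame_index: int
    centroid_px: tuple[float, float]  # (x=col, y=row)
    area_px: int
    area_um2: float
    major_um: float
    minor_um: float
    orientation: float  # chamber-frame body axis, [0, π)

    @property
    def aspect(self) -> float:
        return self.major_um / max(self.minor_um, 1e-12)


@dataclass
class Track:
    """A followed cell: per-frame centroids with derived kinematics."""

    track_id: int
    frame_indices: np.ndarray
    centroid_px: np.ndarray  # (n, 2) as (x=col, y=row)
    orientation: np.ndarray  # chamber-frame body axis per frame
    area_um2: np.ndarray
    aspect: np.ndarray
    status: str = "active"  # {"active", "lost"}
    t_s: np.ndarray | None = None
    centroid_um: np.ndarray | None = None
    speed_um_s: np.ndarray | None = None
    motion_direction: np.ndarray | None = None
    body_orientation: np.ndarray | None = None  # π-ambiguity resolved

    def __post_init__(self) -> None:
        self.frame_indices = np.asarray(self.frame_indices, dtype=int)
        if len(self.frame_indices) > 1 and np.any(np.diff(self.frame_indices) <= 0):
            raise ValueError("frame indices must be strictly increasing")

    def __len__(self) -> int:
        return len(self.frame_indices)


def segment_green(frame: np.ndarray, params: SegmentationParams = SegmentationParams()) -> np.ndarray:
    """Boolean mask of green-dominant pixels in an 8-bit RGB frame."""
    frame = np.asarray(frame)
    if frame.ndim != 3 or frame.shape[-1] != 3:
        raise ValueError("segment_green needs an RGB frame (H, W, 3); channel semantics required")
    rgb = frame.astype(np.int16)
    g = rgb[..., 1]
    other = np.maximum(rgb[..., 0], rgb[..., 2])
    return (g >= params.green_abs_min) & (g - other >= params.green_margin)


def _moment_ellipse(coords: np.ndarray) -> tuple[float, float, float]:
    """(major_px, minor_px, image-frame axis angle) from pixel coords (row, col).

    Axis lengths follow the moment-ellipse convention: full axis = 4·√λ of
    the pixel covariance (exact for a filled ellipse).
    """
    y = coords[:, 0].astype(float)
    x = coords[:, 1].astype(float)
    mu20 = np.var(x) + 1 / 12  # + pixel self-covariance
    mu02 = np.var(y) + 1 / 12
    mu11 = np.mean((x - x.mean()) * (y - y.mean()))
    common = math.sqrt(max((mu20 - mu02) ** 2 + 4 * mu11**2, 0.0))
    lam1 = (mu20 + mu02 + common) / 2
    lam2 = (mu20 + mu02 - common) / 2
    angle_img = 0.5 * math.atan2(2 * mu11, mu20 - mu02)  # y-down frame
    return 4 * math.sqrt(max(lam1, 0)), 4 * math.sqrt(max(lam2, 0)), angle_img


def detect_cells(
    mask: np.ndarray,
    pixel_scale_um: float,
    shape: ShapeFilterParams = ShapeFilterParams(),
    frame_index: int = 0,
) -> list[Detection]:
    """Connected components of a mask, filtered by area and aspect.

    Returns detections sorted by area descending.
    """
    labels = measure.label(np.asarray(mask, dtype=bool), connectivity=2)
    detections: list[Detection] = []
    for region in measure.regionprops(labels):
        area_um2 = region.area * pixel_scale_um**2
        lo, hi = shape.area_range_um2
        if not lo <= area_um2 <= hi:
            continue
        major_px, minor_px, angle_img = _moment_ellipse(region.coords)
        aspect = major_px / max(minor_px, 1e-12)
        if aspect < shape.aspect_min:
            continue
        cy, cx = region.centroid
        detections.append(
            Detection(
                frame_index=frame_index,
                centroid_px=(float(cx), float(cy)),
                area_px=int(region.area),
                area_um2=float(area_um2),
                major_um=major_px * pixel_scale_um,
                minor_um=minor_px * pixel_scale_um,
                orientation=float((-angle_img) % math.pi),
            )
        )
    detections.sort(key=lambda d: -d.area_px)
    return detections


def _nearest_in_roi(
    detections: Sequence[Detection], point: tuple[float, float], radius: float
) -> Detection | None:
    """Nearest detection to ``point`` within ``radius``.

    Tie-break on equal distance: larger area wins, then lower index.
    """
    best = None
    best_key = None
    for idx, det in enumerate(detections):
        d = math.hypot(det.centroid_px[0] - point[0], det.centroid_px[1] - point[1])
        if d > radius:
            continue
        key = (d, -det.area_px, idx)
        if best_key is None or key < best_key:
            best, best_key = det, key
    return best


def track_single(
    detections_by_frame: Sequence[Sequence[Detection]],
    seed_point: tuple[float, float],
    seed_frame: int = 0,
    params: RoiTrackerParams = RoiTrackerParams(),
    track_id: int = 0,
) -> Track:
    """Follow one cell with a nearest-neighbor ROI tracker.

    Binds to the detection nearest ``seed_point`` within the ROI radius at
    ``seed_frame``, then on each later frame to the detection nearest the
    previous centroid.  After ``max_missed_frames`` consecutive frames with
    no detection in the ROI the track is marked lost and truncated at the
    last hit.
    """
    if not 0 <= seed_frame < len(detections_by_frame):
        raise ValueError(f"seed_frame {seed_frame} outside sequence of {len(detections_by_frame)}")
    hit = _nearest_in_roi(detections_by_frame[seed_frame], seed_point, params.roi_radius_px)
    if hit is None:
        raise SelectionError(
            f"no detection within {params.roi_radius_px} px of {seed_point} at frame {seed_frame}"
        )
    frames = [seed_frame]
    dets = [hit]
    status = "active"
    missed = 0
    last = hit.centroid_px
    for f in range(seed_frame + 1, len(detections_by_frame)):
        hit = _nearest_in_roi(detections_by_frame[f], last, params.roi_radius_px)
        if hit is None:
            missed += 1
            if missed > params.max_missed_frames:
                status = "lost"
                break
            continue
        missed = 0
        frames.append(f)
        dets.append(hit)
        last = hit.centroid_px
    return Track(
        track_id=track_id,
        frame_indices=np.array(frames),
        centroid_px=np.array([d.centroid_px for d in dets]),
        orientation=np.array([d.orientation for d in dets]),
        area_um2=np.array([d.area_um2 for d in dets]),
        aspect=np.array([d.aspect for d in dets]),
        status=status,
    )


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    """Centered moving average; the window shrinks symmetrically at the ends."""
    half = window // 2
    out = np.empty_like(values, dtype=float)
    n = len(values)
    for i in range(n):
        w = min(half, i, n - 1 - i)
        out[i] = values[i - w : i + w + 1].mean(axis=0)
    return out


def estimate_kinematics(
    track: Track,
    fps: float,
    pixel_scale_um: float,
    window: int = 5,
    fov_origin_um: tuple[float, float] | None = None,
) -> Track:
    """Fill speed, motion direction, and chamber-frame positions in place.

    The centroid is smoothed with a centered moving average of ``window``
    frames; speed is the centered finite difference of the smoothed centroid
    times pixel scale and frame rate.  The body-axis π-ambiguity is resolved
    toward the motion direction wherever speed exceeds 5 μm/s.
    """
    n = len(track)
    if n < window:
        raise ValueError(f"track length {n} shorter than smoothing window {window}")
    sm = _smooth(track.centroid_px, window)
    # per-sample displacement in chamber frame (y up): dx = +dcol, dy = -drow
    disp = np.empty_like(sm)
    disp[1:-1] = (sm[2:] - sm[:-2]) / 2.0
    disp[0] = sm[1] - sm[0]
    disp[-1] = sm[-1] - sm[-2]
    frame_gap = np.gradient(track.frame_indices.astype(float))
    dx_um = disp[:, 0] * pixel_scale_um
    dy_um = -disp[:, 1] * pixel_scale_um
    track.t_s = track.frame_indices / fps
    track.speed_um_s = np.hypot(dx_um, dy_um) / frame_gap * fps
    track.motion_direction = np.arctan2(dy_um, dx_um)
    if fov_origin_um is not None:
        ox, oy = fov_origin_um
    else:
        ox, oy = 0.0, 0.0
    track.centroid_um = np.column_stack(
        [track.centroid_px[:, 0] * pixel_scale_um + ox,
         oy - track.centroid_px[:, 1] * pixel_scale_um]
    )
    # resolve the axis ambiguity: pick axis or axis+π, whichever is nearer
    # the motion direction, where the cell is clearly moving
    body = track.orientation.copy()
    moving = track.speed_um_s > 5.0
    flipped = wrap_angle(body + np.pi)
    d_axis = np.abs(wrap_angle(body - track.motion_direction))
    d_flip = np.abs(wrap_angle(flipped - track.motion_direction))
    body = np.where(moving & (d_flip < d_axis), flipped, body)
    track.body_orientation = wrap_angle(body)
    return track


def track_video(
    frames: np.ndarray,
    pixel_scale_um: float,
    fps: float,
    seed_points: Sequence[tuple[float, float]] | None = None,
    seg: SegmentationParams = SegmentationParams(),
    shape: ShapeFilterParams = ShapeFilterParams(),
    tracker: RoiTrackerParams = RoiTrackerParams(),
    fov_origin_um: tuple[float, float] | None = None,
) -> list[Track]:
    """Segment, detect, and track through a frame sequence.

    ``seed_points`` selects the cells to follow (pixel coordinates at frame
    0); by default every first-frame detection seeds a track.  Kinematics
    are filled for every track long enough to smooth.
    """
    detections_by_frame = [
        detect_cells(segment_green(frame, seg), pixel_scale_um, shape, frame_index=i)
        for i, frame in enumerate(frames)
    ]
    if seed_points is None:
        seed_points = [d.centroid_px for d in detections_by_frame[0]]
    tracks = []
    for tid, pt in enumerate(seed_points):
        tr = track_single(detections_by_frame, pt, 0, tracker, track_id=tid)
        if len(tr) >= tracker.smoothing_window:
            estimate_kinematics(tr, fps, pixel_scale_um, tracker.smoothing_window, fov_origin_um)
        tracks.append(tr)
    return tracks
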
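"""Synthetic micrograph rendering of simulated swimmer populations.

Emulates the transmitted-light camera view of the physical instrument:
bright diffusely-lit background, elongated green cells (~50–80 μm long)
drawn as anti-aliased filled ellipses oriented along their heading.
The renderer honors sub-pixel positions (4× supersampled coverage) so a
tracking pipeline can be validated against exact ground truth.

Image convention: origin top-left, y down.  The chamber frame has y up,
so a heading ``theta`` maps to image-plane angle ``−theta``.  The field of
view is a window of the chamber given by ``fov_origin_um`` — the chamber
coordinate of the center of pixel (0, 0).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

from microswim.sim import AgentState, SimTrack

__all__ = [
    "ImagingConfig",
    "FrameStack",
    "render_frame",
    "render_sequence",
    "chamber_to_pixel",
    "pixel_to_chamber",
]

_SUPERSAMPLE = 4


@dataclass(frozen=True)
class ImagingConfig:
    """Camera and specimen appearance parameters.

    ``cell_color`` must be green-dominant (G > max(R, B)) so rendered cells
    satisfy a green-channel segmentation predicate; the background is a
    neutral bright gray.
    """

    pixel_scale_um: float = 2.0
    frame_size: tuple[int, int] = (640, 480)  # (width, height) px
    fps: float = 10.0
    cell_length_range_um: tuple[float, float] = (50.0, 80.0)
    cell_width_range_um: tuple[float, float] = (8.0, 15.0)
    cell_color: tuple[int, int, int] = (30, 140, 30)
    background_gray: int = 220
    noise_sigma: float = 0.0
    fov_origin_um: tuple[float, float] | None = None  # default: centered window

    def __post_init__(self) -> None:
        if self.pixel_scale_um <= 0 or self.fps <= 0:
            raise ValueError("pixel_scale_um and fps must be positive")
        r, g, b = self.cell_color
        if not g > max(r, b):
            raise ValueError("cell_color must be green-dominant (G > max(R, B))")
        lo, hi = self.cell_length_range_um
        wlo, whi = self.cell_width_range_um
        if not (0 < lo <= hi and 0 < wlo <= whi):
            raise ValueError("cell size ranges must be positive and ordered")
        if not 0 <= self.noise_sigma:
            raise ValueError("noise_sigma must be non-negative")

    @property
    def origin(self) -> tuple[float, float]:
        """Chamber coordinate (μm) of the center of pixel (0, 0)."""
        if self.fov_origin_um is not None:
            return self.fov_origin_um
        w, h = self.frame_size
        return (-w / 2.0 * self.pixel_scale_um, h / 2.0 * self.pixel_scale_um)

    def draw_cell_sizes(self, n: int, rng: np.random.Generator) -> np.ndarray:
        """Sample (length, width) μm pairs for n cells, uniform in the ranges."""
        lengths = rng.uniform(*self.cell_length_range_um, size=n)
        widths = rng.uniform(*self.cell_width_range_um, size=n)
        return np.column_stack([lengths, widths])


def chamber_to_pixel(cfg: ImagingConfig, x_um, y_um) -> tuple[np.ndarray, np.ndarray]:
    """Chamber-frame μm → (col, row) pixel coordinates (float, sub-pixel)."""
    ox, oy = cfg.origin
    px = (np.asarray(x_um, dtype=float) - ox) / cfg.pixel_scale_um
    py = (oy - np.asarray(y_um, dtype=float)) / cfg.pixel_scale_um
    return px, py


def pixel_to_chamber(cfg: ImagingConfig, px, py) -> tuple[np.ndarray, np.ndarray]:
    """(col, row) pixel coordinates → chamber-frame μm."""
    ox, oy = cfg.origin
    x = np.asarray(px, dtype=float) * cfg.pixel_scale_um + ox
    y = oy - np.asarray(py, dtype=float) * cfg.pixel_scale_um
    return x, y


@dataclass
class FrameStack:
    """An ordered RGB frame sequence with the metadata needed to track it."""

    frames: np.ndarray  # (n_frames, H, W, 3) uint8
    fps: float
    pixel_scale_um: float
    fov_origin_um: tuple[float, float]
    seed: int | None = None
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 4 or self.frames.shape[-1] != 3:
            raise ValueError("frames must have shape (n, H, W, 3)")

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def metadata(self) -> dict:
        return {
            "pixel_scale_um": self.pixel_scale_um,
            "fps": self.fps,
            "fov_origin_um": list(self.fov_origin_um),
            "seed": self.seed,
            **self.extra,
        }

    def save(self, path: str | Path) -> None:
        """Write a multi-page TIFF plus a sidecar JSON metadata file."""
        path = Path(path)
        tifffile.imwrite(path, self.frames, photometric="rgb")
        path.with_suffix(".json").write_text(json.dumps(self.metadata, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "FrameStack":
        path = Path(path)
        frames = tifffile.imread(path)
        if frames.ndim == 3:  # single page
            frames = frames[None]
        meta = json.loads(path.with_suffix(".json").read_text())
        return cls(
            frames=frames,
            fps=meta["fps"],
            pixel_scale_um=meta["pixel_scale_um"],
            fov_origin_um=tuple(meta["fov_origin_um"]),
            seed=meta.get("seed"),
            extra={k: v for k, v in meta.items() if k not in
                   {"fps", "pixel_scale_um", "fov_origin_um", "seed"}},
        )


def _ellipse_coverage(
    width: int,
    height: int,
    center_px: tuple[float, float],
    half_axes_px: tuple[float, float],
    angle_img: float,
) -> tuple[slice, slice, np.ndarray] | None:
    """Supersampled coverage of a rotated ellipse; None if outside the frame."""
    cx, cy = center_px
    a, b = half_axes_px
    r = max(a, b) + 1.5
    x0, x1 = int(math.floor(cx - r)), int(math.ceil(cx + r)) + 1
    y0, y1 = int(math.floor(cy - r)), int(math.ceil(cy + r)) + 1
    x0, x1 = max(x0, 0), min(x1, width)
    y0, y1 = max(y0, 0), min(y1, height)
    if x0 >= x1 or y0 >= y1:
        return None
    s = _SUPERSAMPLE
    sub = (np.arange(s) + 0.5) / s - 0.5
    xs = (np.arange(x0, x1)[:, None] + sub[None, :]).ravel()
    ys = (np.arange(y0, y1)[:, None] + sub[None, :]).ravel()
    dx = xs[None, :] - cx  # (ny*s applied below) — build full grid
    dy = ys[:, None] - cy
    ca, sa = math.cos(angle_img), math.sin(angle_img)
    u = ca * dx + sa * dy
    w = -sa * dx + ca * dy
    inside = (u / a) ** 2 + (w / b) ** 2 <= 1.0
    ny, nx = y1 - y0, x1 - x0
    cov = inside.reshape(ny, s, nx, s).mean(axis=(1, 3))
    return slice(y0, y1), slice(x0, x1), cov


def render_frame(
    agents: Sequence[AgentState],
    cfg: ImagingConfig,
    rng: np.random.Generator | None = None,
    sizes_um: np.ndarray | None = None,
) -> np.ndarray:
    """Render one RGB frame (H, W, 3 uint8) of the given agents.

    Each in-view agent is drawn as a filled anti-aliased ellipse with major
    axis equal to its body length, oriented along its heading.  ``sizes_um``
    fixes per-agent (length, width); otherwise sizes are drawn from ``rng``
    (or range midpoints if no rng is given).  Gaussian pixel noise with
    ``cfg.noise_sigma`` is added last.
    """
    w, h = cfg.frame_size
    img = np.full((h, w, 3), float(cfg.background_gray))
    if sizes_um is None:
        if rng is not None and len(agents) > 0:
            sizes_um = cfg.draw_cell_sizes(len(agents), rng)
        else:
            sizes_um = np.tile(
                [np.mean(cfg.cell_length_range_um), np.mean(cfg.cell_width_range_um)],
                (len(agents), 1),
            )
    color = np.asarray(cfg.cell_color, dtype=float)
    for agent, (length, width_um) in zip(agents, sizes_um):
        x, y = agent.position
        px, py = chamber_to_pixel(cfg, x, y)
        half_axes = (length / 2 / cfg.pixel_scale_um, width_um / 2 / cfg.pixel_scale_um)
        patch = _ellipse_coverage(w, h, (float(px), float(py)), half_axes, -agent.heading)
        if patch is None:
            continue
        rows, cols, cov = patch
        alpha = cov[..., None]
        img[rows, cols] = img[rows, cols] * (1 - alpha) + color * alpha
    if cfg.noise_sigma > 0:
        if rng is None:
            raise ValueError("noise_sigma > 0 requires an rng")
        img += rng.normal(0.0, cfg.noise_sigma, size=img.shape)
    return np.clip(np.round(img), 0, 255).astype(np.uint8)


def render_sequence(
    tracks: Sequence[SimTrack],
    cfg: ImagingConfig,
    seed: int | np.random.Generator = 0,
) -> FrameStack:
    """Render a frame sequence from simulated tracks.

    One frame per 1/fps; frame count = floor(duration · fps) + 1.  The track
    sampling rate must be at least ``cfg.fps`` and all tracks must share the
    same time base.  Per-agent body sizes are drawn once and held fixed
    across frames; deterministic given ``seed``.
    """
    if not tracks:
        raise ValueError("render_sequence needs at least one track")
    n = len(tracks[0])
    if any(len(tr) != n for tr in tracks):
        raise ValueError("all tracks must have the same length")
    t = tracks[0].t_s
    if any(not np.allclose(tr.t_s, t) for tr in tracks):
        raise ValueError("all tracks must share the same time base")
    duration = float(t[-1] - t[0])
    if n > 1:
        dt = float(t[1] - t[0])
        if 1.0 / dt < cfg.fps - 1e-9:
            raise ValueError(
                f"track sampling rate {1.0 / dt:.3g}/s is below fps {cfg.fps}"
            )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_val = None if isinstance(seed, np.random.Generator) else int(seed)
    sizes = cfg.draw_cell_sizes(len(tracks), rng)
    n_frames = int(math.floor(duration * cfg.fps + 1e-9)) + 1
    frames = np.empty((n_frames, cfg.frame_size[1], cfg.frame_size[0], 3), dtype=np.uint8)
    for j in range(n_frames):
        tf = t[0] + j / cfg.fps
        idx = int(np.argmin(np.abs(t - tf)))
        agents = [
            AgentState(
                position=(tr.x_um[idx], tr.y_um[idx]),
                heading=tr.heading_rad[idx],
                agent_id=tr.agent_id,
            )
            for tr in tracks
        ]
        frames[j] = render_frame(agents, cfg, rng=rng, sizes_um=sizes)
    return FrameStack(
        frames=frames,
        fps=cfg.fps,
        pixel_scale_um=cfg.pixel_scale_um,
        fov_origin_um=cfg.origin,
        seed=seed_val,
        extra={"n_agents": len(tracks)},
    )
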
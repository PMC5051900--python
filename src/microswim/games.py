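"""Headless game engines driven by a tracked (or simulated) cell.

Two games:

* **Soccer** — the cell dribbles or shoots a virtual ball into a goal.
  Carrying or shooting the ball into the goal scores 5 points; tapping the
  screen to pick up the ball costs 1 point; the scoring goal switches sides
  every 30 seconds.  The ball, when carried, rides a fixed lead distance
  ahead of the cell along its motion direction.
* **Maze** — the cell must visit an ordered list of waypoints; the swimming
  path is recorded and compared with the designated path at the end.

Both engines are frame-driven and deterministic: replaying the same cell
track and event script reproduces the same final state.  Field coordinates
are screen pixels (origin top-left, y down), matching the tracking module's
pixel frame.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import LineString, Point

__all__ = [
    "SoccerConfig",
    "SoccerState",
    "MazeGame",
    "GameEvent",
    "CellSample",
    "soccer_step",
    "projected_path",
    "segment_hits_rect",
    "maze_step",
    "path_report",
    "play_soccer",
]


@dataclass(frozen=True)
class SoccerConfig:
    """Scoring and geometry constants of the soccer game."""

    goal_points: int = 5
    tap_cost: int = 1
    goal_switch_period_s: float = 30.0
    pickup_radius_px: float = 30.0
    shoot_distance_px: float = 300.0
    ball_lead_px: float = 25.0
    field_size_px: tuple[float, float] = (640.0, 480.0)
    goal_width_px: float = 20.0
    goal_height_px: float = 160.0


@dataclass(frozen=True)
class GameEvent:
    t_s: float
    kind: Literal["tap_select", "shoot", "none"] = "none"
    x: float = 0.0
    y: float = 0.0


@dataclass(frozen=True)
class CellSample:
    """Cell state handed to the engine each step (pixel frame)."""

    position: tuple[float, float]
    motion_direction: float  # radians; pixel frame (y down)
    speed: float = 0.0


@dataclass
class SoccerState:
    score: int = 0
    ball_state: Literal["free", "carried"] = "free"
    ball_position: tuple[float, float] = (320.0, 240.0)
    goal_side: Literal["left", "right"] = "right"
    clock_s: float = 0.0
    goals: int = 0
    taps: int = 0
    config: SoccerConfig = field(default_factory=SoccerConfig)

    @property
    def goal_rect(self) -> tuple[float, float, float, float]:
        """(x0, y0, x1, y1) of the current scoring goal."""
        w, h = self.config.field_size_px
        gw, gh = self.config.goal_width_px, self.config.goal_height_px
        y0, y1 = (h - gh) / 2, (h + gh) / 2
        if self.goal_side == "left":
            return (0.0, y0, gw, y1)
        return (w - gw, y0, w, y1)

    def field_center(self) -> tuple[float, float]:
        w, h = self.config.field_size_px
        return (w / 2, h / 2)


def _in_rect(p: tuple[float, float], rect: tuple[float, float, float, float]) -> bool:
    x0, y0, x1, y1 = rect
    return x0 <= p[0] <= x1 and y0 <= p[1] <= y1


def segment_hits_rect(
    origin: tuple[float, float],
    direction: float,
    length: float,
    rect: tuple[float, float, float, float],
) -> bool:
    """True iff the segment from ``origin`` of ``length`` along ``direction``
    intersects the axis-aligned rectangle (slab clipping)."""
    ox, oy = origin
    dx, dy = math.cos(direction), math.sin(direction)
    t0, t1 = 0.0, length
    for o, d, lo, hi in ((ox, dx, rect[0], rect[2]), (oy, dy, rect[1], rect[3])):
        if abs(d) < 1e-12:
            if not lo <= o <= hi:
                return False
            continue
        ta, tb = (lo - o) / d, (hi - o) / d
        if ta > tb:
            ta, tb = tb, ta
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return False
    return True


def projected_path(cell: CellSample) -> tuple[tuple[float, float], float]:
    """The shot ray: (origin, direction) from the cell's current motion.

    Undefined (raises) for a stationary cell.
    """
    if cell.speed <= 0:
        raise ValueError("projected path undefined for a stationary cell (speed 0)")
    return cell.position, cell.motion_direction


def _score_goal(state: SoccerState) -> None:
    state.goals += 1
    state.score += state.config.goal_points
    state.ball_state = "free"
    state.ball_position = state.field_center()


def soccer_step(
    state: SoccerState,
    cell: CellSample,
    events: Sequence[GameEvent] = (),
    dt: float = 0.1,
) -> SoccerState:
    """Advance the soccer game by ``dt`` seconds.

    ``events`` are those falling in the step window (clock, clock + dt];
    they must be in time order.  Rules: the goal side toggles at each
    30-second boundary; a free ball is picked up when the cell comes within
    the pickup radius, or anywhere via a tap (costing 1 point); a carried
    ball rides ``ball_lead_px`` ahead of the cell and scores when it enters
    the goal; a shot sends the ball ``shoot_distance_px`` along the motion
    direction and scores iff that segment crosses the goal.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if any(events[i].t_s > events[i + 1].t_s for i in range(len(events) - 1)):
        raise ValueError("events out of time order")
    cfg = state.config
    new = replace(
        state,
        ball_position=tuple(state.ball_position),
        config=cfg,
    )
    t0 = new.clock_s
    new.clock_s = t0 + dt
    # goal side toggles at every multiple of the switch period crossed
    n_toggles = math.floor(new.clock_s / cfg.goal_switch_period_s + 1e-9) - math.floor(
        t0 / cfg.goal_switch_period_s + 1e-9
    )
    for _ in range(n_toggles):
        new.goal_side = "left" if new.goal_side == "right" else "right"

    for ev in events:
        if ev.kind == "tap_select":
            new.taps += 1
            new.score -= cfg.tap_cost
            new.ball_state = "carried"
        elif ev.kind == "shoot":
            if new.ball_state == "carried" and cell.speed > 0:
                origin, direction = projected_path(
                    CellSample(new.ball_position, cell.motion_direction, cell.speed)
                )
                end = (
                    origin[0] + cfg.shoot_distance_px * math.cos(direction),
                    origin[1] + cfg.shoot_distance_px * math.sin(direction),
                )
                if segment_hits_rect(origin, direction, cfg.shoot_distance_px, new.goal_rect):
                    _score_goal(new)
                else:
                    new.ball_state = "free"
                    new.ball_position = end

    if new.ball_state == "free":
        d = math.hypot(
            cell.position[0] - new.ball_position[0],
            cell.position[1] - new.ball_position[1],
        )
        if d <= cfg.pickup_radius_px:
            new.ball_state = "carried"
    if new.ball_state == "carried":
        new.ball_position = (
            cell.position[0] + cfg.ball_lead_px * math.cos(cell.motion_direction),
            cell.position[1] + cfg.ball_lead_px * math.sin(cell.motion_direction),
        )
        if _in_rect(new.ball_position, new.goal_rect):
            _score_goal(new)
    return new


def play_soccer(
    cell_samples: Sequence[CellSample],
    events: Sequence[GameEvent],
    dt: float = 0.1,
    initial: SoccerState | None = None,
) -> tuple[SoccerState, list[dict]]:
    """Replay a full game from per-step cell samples and an event script.

    Returns the final state and a per-step log of
    (t_s, score, ball_state, goal_side).
    """
    state = initial if initial is not None else SoccerState()
    events = sorted(events, key=lambda e: e.t_s)
    log = []
    ei = 0
    for cell in cell_samples:
        t1 = state.clock_s + dt
        step_events = []
        while ei < len(events) and events[ei].t_s <= t1 + 1e-9:
            step_events.append(events[ei])
            ei += 1
        state = soccer_step(state, cell, step_events, dt)
        log.append(
            {
                "t_s": state.clock_s,
                "score": state.score,
                "ball_state": state.ball_state,
                "goal_side": state.goal_side,
            }
        )
    return state, log


@dataclass
class MazeGame:
    """Ordered-waypoint maze: waypoints must be collected in sequence."""

    waypoints: list[tuple[float, float]]
    capture_radius_px: float = 20.0
    designated_path: list[tuple[float, float]] | None = None
    collected: int = 0
    recorded_path: list[tuple[float, float, float]] = field(default_factory=list)  # (t, x, y)

    def __post_init__(self) -> None:
        if not self.waypoints:
            raise ValueError("maze needs at least one waypoint")
        if self.capture_radius_px <= 0:
            raise ValueError("capture_radius_px must be positive")
        if self.designated_path is None:
            self.designated_path = list(self.waypoints)

    @property
    def complete(self) -> bool:
        return self.collected == len(self.waypoints)


def maze_step(game: MazeGame, cell_position: tuple[float, float], t_s: float) -> MazeGame:
    """Record the cell position and collect the next waypoint if reached.

    Waypoints are strictly ordered: passing near a later waypoint first
    does not collect it.
    """
    if game.recorded_path and t_s < game.recorded_path[-1][0]:
        raise ValueError("timestamps must be non-decreasing")
    game.recorded_path.append((float(t_s), float(cell_position[0]), float(cell_position[1])))
    if not game.complete:
        wx, wy = game.waypoints[game.collected]
        if math.hypot(cell_position[0] - wx, cell_position[1] - wy) <= game.capture_radius_px:
            game.collected += 1
    return game


def path_report(game: MazeGame) -> dict:
    """Post-game summary: the recorded trace and its mean minimum distance
    to the designated polyline."""
    if not game.recorded_path:
        raise ValueError("no recorded path: the game has not been played")
    trace = np.array(game.recorded_path)
    line = LineString(game.designated_path)
    dists = [line.distance(Point(x, y)) for _, x, y in game.recorded_path]
    return {
        "trace": trace,
        "mean_min_distance": float(np.mean(dists)),
        "collected": game.collected,
        "complete": game.complete,
    }
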
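"""Stochastic agent-based phototaxis model in a 2D chamber under four LEDs.

The model advances each swimmer's heading ``theta`` and position ``(x, y)``
with an Euler–Maruyama scheme:

.. math::

    d\\theta = k\\,I\\,\\sin(\\phi^* - \\theta)\\,dt + \\sqrt{2 D_r\\,dt}\\,\\eta

    dx = v\\cos\\theta\\,dt, \\qquad dy = v\\sin\\theta\\,dt

where ``I = |L|`` is the magnitude of the net light stimulus vector ``L``
(sum of the four LED levels times their inward propagation directions),
``phi*`` is the preferred heading — along the propagation direction for a
negatively phototactic swimmer (it flees the sources) and opposite for a
positive one — ``k`` is the turning sensitivity, ``D_r`` the rotational
diffusivity ("noisiness of the swimming path") and ``eta`` a standard
normal increment.  Walls reflect: position is mirrored and the heading is
reflected about the wall normal.

Coordinates: chamber frame, origin at the chamber center, x to the right,
y up, angles CCW from +x, wrapped to (−π, π].  LED labels Left/Right/Up/Down
name the chamber edge each LED sits on, so the Left LED propagates toward
+x, Right toward −x, Up toward −y, Down toward +y.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "MotilityParams",
    "AgentState",
    "LightField",
    "StimulusSchedule",
    "SimTrack",
    "LED_DIRECTIONS",
    "LED_ORDER",
    "net_stimulus",
    "step_agent",
    "simulate",
    "simulate_ensemble",
    "wrap_angle",
]

#: LED label order used everywhere levels appear as a 4-vector.
LED_ORDER = ("left", "right", "up", "down")

#: Inward propagation direction of each LED in the chamber frame (y up).
LED_DIRECTIONS = {
    "left": np.array([1.0, 0.0]),
    "right": np.array([-1.0, 0.0]),
    "up": np.array([0.0, -1.0]),
    "down": np.array([0.0, 1.0]),
}

_LED_DIR_MATRIX = np.array([LED_DIRECTIONS[name] for name in LED_ORDER])  # (4, 2)


def wrap_angle(theta):
    """Wrap an angle (scalar or array) to the interval (−π, π]."""
    return np.pi - np.mod(np.pi - np.asarray(theta), 2.0 * np.pi)


@dataclass(frozen=True)
class MotilityParams:
    """Motility parameters of one swimmer species.

    Parameters
    ----------
    speed_um_s : float
        Swimming speed v in μm/s, ≥ 0.
    turn_sensitivity : float
        k, heading realignment rate per unit light intensity (rad/s).
    rot_noise : float
        Rotational diffusivity D_r in rad²/s.
    taxis_sign : int
        −1 for negative phototaxis (Euglena at high intensity),
        +1 for positive phototaxis (Volvox).
    """

    speed_um_s: float = 50.0
    turn_sensitivity: float = 1.0
    rot_noise: float = 0.3
    taxis_sign: int = -1

    def __post_init__(self) -> None:
        for name in ("speed_um_s", "turn_sensitivity", "rot_noise"):
            value = getattr(self, name)
            if not math.isfinite(value) or value < 0:
                raise ValueError(f"{name} must be finite and non-negative, got {value}")
        if self.taxis_sign not in (-1, 1):
            raise ValueError(f"taxis_sign must be -1 or +1, got {self.taxis_sign}")


@dataclass
class AgentState:
    """Instantaneous state of one simulated swimmer (chamber frame, μm)."""

    position: tuple[float, float]
    heading: float
    params: MotilityParams = field(default_factory=MotilityParams)
    agent_id: int = 0

    def __post_init__(self) -> None:
        x, y = self.position
        if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(self.heading)):
            raise ValueError("agent state must be finite")
        self.heading = float(wrap_angle(self.heading))


@dataclass
class LightField:
    """Four directional LEDs aimed at the chamber center, plus background light.

    ``led_levels`` are the (left, right, up, down) drive levels in [0, 1];
    values outside are clamped.  The default is a collimated-beam
    approximation (no distance falloff, the LEDs being far compared to the
    6.5 mm chamber); ``distance_falloff=True`` switches on an optional
    inverse-distance attenuation from each edge midpoint.
    """

    chamber_side_um: float = 6500.0
    led_levels: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    illumination_level: float = 1.0
    distance_falloff: bool = False

    def __post_init__(self) -> None:
        if self.chamber_side_um <= 0:
            raise ValueError("chamber_side_um must be positive")
        levels = np.clip(np.asarray(self.led_levels, dtype=float), 0.0, 1.0)
        if levels.shape != (4,):
            raise ValueError("led_levels must have 4 entries (left, right, up, down)")
        self.led_levels = tuple(float(v) for v in levels)
        self.illumination_level = float(np.clip(self.illumination_level, 0.0, 1.0))

    @property
    def half_side(self) -> float:
        return self.chamber_side_um / 2.0

    def contains(self, position) -> bool:
        x, y = position
        h = self.half_side
        return -h <= x <= h and -h <= y <= h

    def with_levels(self, led_levels) -> "LightField":
        return replace(self, led_levels=tuple(led_levels))

    def _edge_midpoints(self) -> np.ndarray:
        h = self.half_side
        return np.array([[-h, 0.0], [h, 0.0], [0.0, h], [0.0, -h]])

    def stimulus(self, positions: np.ndarray) -> np.ndarray:
        """Net stimulus vectors at ``positions`` (n, 2) → (n, 2)."""
        positions = np.asarray(positions, dtype=float)
        levels = np.asarray(self.led_levels)
        if not self.distance_falloff:
            L = levels @ _LED_DIR_MATRIX
            return np.broadcast_to(L, positions.shape).copy()
        mids = self._edge_midpoints()
        d = np.linalg.norm(positions[:, None, :] - mids[None, :, :], axis=2)
        scale = self.half_side / np.maximum(d, 1e-9)
        return (levels * scale) @ _LED_DIR_MATRIX


@dataclass
class StimulusSchedule:
    """Timed LED program: ordered (t0, t1, levels) intervals covering [0, T]."""

    intervals: list[tuple[float, float, tuple[float, float, float, float]]]

    def __post_init__(self) -> None:
        if not self.intervals:
            raise ValueError("schedule must contain at least one interval")
        t_prev = 0.0
        cleaned = []
        for t0, t1, levels in self.intervals:
            if not math.isclose(t0, t_prev, abs_tol=1e-9):
                raise ValueError(
                    f"intervals must tile [0, T] without gaps: got start {t0}, expected {t_prev}"
                )
            if t1 < t0 or (t1 == t0 and len(self.intervals) > 1):
                # a single zero-length interval encodes an empty (duration-0) program
                raise ValueError(f"interval ({t0}, {t1}) has non-positive length")
            levels = tuple(float(v) for v in levels)
            if len(levels) != 4:
                raise ValueError("each interval needs 4 LED levels")
            cleaned.append((float(t0), float(t1), levels))
            t_prev = t1
        self.intervals = cleaned

    @property
    def duration(self) -> float:
        return self.intervals[-1][1]

    def levels_at(self, t: float) -> tuple[float, float, float, float]:
        """LED levels applied during the step starting at time ``t``.

        Boundaries belong to the interval that starts there; the final
        endpoint returns the last interval's levels.
        """
        if t < -1e-9 or t > self.duration + 1e-9:
            raise ValueError(f"time {t} outside schedule span [0, {self.duration}]")
        for t0, t1, levels in self.intervals:
            if t < t1 - 1e-9:
                return levels
        return self.intervals[-1][2]

    @classmethod
    def constant(cls, levels, duration_s: float) -> "StimulusSchedule":
        return cls([(0.0, float(duration_s), tuple(levels))])

    @classmethod
    def responsiveness_protocol(cls, interval_s: float = 10.0, level: float = 1.0) -> "StimulusSchedule":
        """The 8-direction assay program: L, R, U, D, R, D, L, U, one LED at a time."""
        sequence = ["left", "right", "up", "down", "right", "down", "left", "up"]
        intervals = []
        for i, name in enumerate(sequence):
            levels = [0.0, 0.0, 0.0, 0.0]
            levels[LED_ORDER.index(name)] = level
            intervals.append((i * interval_s, (i + 1) * interval_s, tuple(levels)))
        return cls(intervals)


@dataclass
class SimTrack:
    """Sampled trajectory of one agent: t (s), x/y (μm), heading (rad)."""

    agent_id: int
    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    heading_rad: np.ndarray

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        self.heading_rad = np.asarray(self.heading_rad, dtype=float)
        n = len(self.t_s)
        if not (len(self.x_um) == len(self.y_um) == len(self.heading_rad) == n):
            raise ValueError("track arrays must have equal length")
        if n > 1 and np.any(np.diff(self.t_s) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def __len__(self) -> int:
        return len(self.t_s)

    @property
    def positions(self) -> np.ndarray:
        return np.column_stack([self.x_um, self.y_um])


def net_stimulus(field: LightField, position) -> np.ndarray:
    """Net light stimulus vector L at ``position``.

    L = Σ_j level_j · u_j with u_j the j-th LED's inward propagation
    direction; |L| is the local intensity and L/|L| the propagation
    direction.  Raises ``ValueError`` for positions outside the chamber.
    """
    if not field.contains(position):
        raise ValueError(f"position {position} outside chamber of side {field.chamber_side_um} μm")
    return field.stimulus(np.asarray(position, dtype=float)[None, :])[0]


def _reflect(positions: np.ndarray, headings: np.ndarray, half: float) -> None:
    """Reflect positions/headings at the square chamber walls, in place."""
    for _ in range(64):  # bound: each pass halves the overshoot span
        out = False
        for axis, flip in ((0, lambda th: np.pi - th), (1, lambda th: -th)):
            over = positions[:, axis] > half
            under = positions[:, axis] < -half
            if over.any():
                positions[over, axis] = 2 * half - positions[over, axis]
                headings[over] = flip(headings[over])
                out = True
            if under.any():
                positions[under, axis] = -2 * half - positions[under, axis]
                headings[under] = flip(headings[under])
                out = True
        if not out:
            return
    raise RuntimeError("reflection did not converge; step displacement exceeds chamber size")


def _advance(
    positions: np.ndarray,
    headings: np.ndarray,
    v: np.ndarray,
    k: np.ndarray,
    dr: np.ndarray,
    sign: np.ndarray,
    field: LightField,
    dt: float,
    rng: np.random.Generator,
) -> None:
    """One Euler–Maruyama step for an ensemble, in place."""
    L = field.stimulus(positions)
    intensity = np.hypot(L[:, 0], L[:, 1])
    lit = intensity > 0
    if lit.any():
        # preferred heading: along propagation for negative taxis, opposite for positive
        pref = np.arctan2(-sign[lit] * L[lit, 1], -sign[lit] * L[lit, 0])
        headings[lit] = headings[lit] + k[lit] * intensity[lit] * np.sin(pref - headings[lit]) * dt
    headings += np.sqrt(2.0 * dr * dt) * rng.standard_normal(len(headings))
    headings[:] = wrap_angle(headings)
    positions[:, 0] += v * np.cos(headings) * dt
    positions[:, 1] += v * np.sin(headings) * dt
    _reflect(positions, headings, field.half_side)
    headings[:] = wrap_angle(headings)


def step_agent(
    state: AgentState,
    field: LightField,
    dt: float,
    rng: np.random.Generator,
) -> AgentState:
    """Advance a single agent by one time step ``dt`` (seconds)."""
    if dt <= 0:
        raise ValueError("dt must be positive")
    x, y = state.position
    if not (math.isfinite(x) and math.isfinite(y) and math.isfinite(state.heading)):
        raise ValueError("non-finite agent state")
    positions = np.array([[x, y]], dtype=float)
    headings = np.array([state.heading], dtype=float)
    p = state.params
    _advance(
        positions,
        headings,
        np.array([p.speed_um_s]),
        np.array([p.turn_sensitivity]),
        np.array([p.rot_noise]),
        np.array([float(p.taxis_sign)]),
        field,
        dt,
        rng,
    )
    return AgentState(
        position=(float(positions[0, 0]), float(positions[0, 1])),
        heading=float(headings[0]),
        params=p,
        agent_id=state.agent_id,
    )


def simulate_ensemble(
    positions: np.ndarray,
    headings: np.ndarray,
    params: MotilityParams | Sequence[MotilityParams],
    schedule: StimulusSchedule,
    dt: float,
    rng: np.random.Generator,
    field: LightField | None = None,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized simulation of n agents under a stimulus schedule.

    Returns ``(t, pos, theta)`` with shapes (m,), (m, n, 2), (m, n) where
    m = round(duration/dt) + 1.  All agents share the RNG stream, so
    results are deterministic for a given generator state.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    positions = np.array(positions, dtype=float)
    headings = wrap_angle(np.array(headings, dtype=float))
    n = len(headings)
    if isinstance(params, MotilityParams):
        params = [params] * n
    v = np.array([p.speed_um_s for p in params], dtype=float)
    k = np.array([p.turn_sensitivity for p in params], dtype=float)
    dr = np.array([p.rot_noise for p in params], dtype=float)
    sign = np.array([float(p.taxis_sign) for p in params], dtype=float)
    if field is None:
        field = LightField()
    n_steps = round(schedule.duration / dt)
    if not math.isclose(n_steps * dt, schedule.duration, rel_tol=1e-9, abs_tol=1e-9):
        raise ValueError(f"dt={dt} does not divide schedule duration {schedule.duration}")
    for t0, t1, _ in schedule.intervals:
        length = t1 - t0
        if not math.isclose(round(length / dt) * dt, length, rel_tol=1e-9, abs_tol=1e-9):
            raise ValueError(f"dt={dt} does not divide interval length {length}")
    t = np.arange(n_steps + 1) * dt
    pos_out = np.empty((n_steps + 1, n, 2))
    theta_out = np.empty((n_steps + 1, n))
    pos_out[0] = positions
    theta_out[0] = headings
    for i in range(n_steps):
        stepped = field.with_levels(schedule.levels_at(t[i]))
        _advance(positions, headings, v, k, dr, sign, stepped, dt, rng)
        pos_out[i + 1] = positions
        theta_out[i + 1] = headings
    return t, pos_out, theta_out


def simulate(
    population: Sequence[AgentState],
    schedule: StimulusSchedule,
    dt: float = 0.1,
    seed: int | np.random.Generator = 0,
    field: LightField | None = None,
) -> list[SimTrack]:
    """Simulate a population under a stimulus schedule; one SimTrack per agent.

    Deterministic given ``seed``; each track has round(duration/dt) + 1
    samples at a constant step.  An empty population yields an empty list.
    """
    if not population:
        return []
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    positions = np.array([a.position for a in population], dtype=float)
    headings = np.array([a.heading for a in population], dtype=float)
    params = [a.params for a in population]
    t, pos, theta = simulate_ensemble(positions, headings, params, schedule, dt, rng, field)
    return [
        SimTrack(
            agent_id=a.agent_id,
            t_s=t,
            x_um=pos[:, i, 0],
            y_um=pos[:, i, 1],
            heading_rad=theta[:, i],
        )
        for i, a in enumerate(population)
    ]
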
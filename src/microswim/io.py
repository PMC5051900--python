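"""Readers/writers for track tables, schedules, and event scripts.

All formats are plain text: CSV for trajectories and game logs, JSON for
stimulus schedules and user-event scripts.  Readers validate headers and
report the offending line number on malformed input.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from microswim.games import GameEvent
from microswim.sim import SimTrack, StimulusSchedule
from microswim.tracking import Track

__all__ = [
    "ParseError",
    "write_sim_tracks",
    "read_sim_tracks",
    "write_tracks",
    "read_tracks",
    "write_schedule",
    "read_schedule",
    "write_events",
    "read_events",
    "write_game_log",
]

SIM_TRACK_COLUMNS = ["agent_id", "t_s", "x_um", "y_um", "heading_rad"]
TRACK_COLUMNS = [
    "track_id",
    "frame",
    "t_s",
    "x_um",
    "y_um",
    "speed_um_s",
    "motion_dir_rad",
    "body_orient_rad",
    "area_um2",
    "aspect",
]


class ParseError(ValueError):
    """Malformed input file; carries the 1-based line number when known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        super().__init__(f"line {line}: {message}" if line is not None else message)


def _check_header(actual: list[str], expected: list[str], path) -> None:
    missing = [c for c in expected if c not in actual]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}", line=1)


def write_sim_tracks(tracks: list[SimTrack], path: str | Path) -> None:
    frames = [
        pd.DataFrame(
            {
                "agent_id": tr.agent_id,
                "t_s": tr.t_s,
                "x_um": tr.x_um,
                "y_um": tr.y_um,
                "heading_rad": tr.heading_rad,
            }
        )
        for tr in tracks
    ]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(columns=SIM_TRACK_COLUMNS)
    df.to_csv(path, index=False, float_format="%.10g")


def read_sim_tracks(path: str | Path) -> list[SimTrack]:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ParseError(str(e)) from e
    _check_header(list(df.columns), SIM_TRACK_COLUMNS, path)
    tracks = []
    for agent_id, g in df.groupby("agent_id", sort=True):
        tracks.append(
            SimTrack(
                agent_id=int(agent_id),
                t_s=g["t_s"].to_numpy(),
                x_um=g["x_um"].to_numpy(),
                y_um=g["y_um"].to_numpy(),
                heading_rad=g["heading_rad"].to_numpy(),
            )
        )
    return tracks


def write_tracks(tracks: list[Track], path: str | Path) -> None:
    """Write measured tracks (chamber-frame kinematics) as CSV."""
    rows = []
    for tr in tracks:
        for i in range(len(tr)):
            rows.append(
                {
                    "track_id": tr.track_id,
                    "frame": int(tr.frame_indices[i]),
                    "t_s": None if tr.t_s is None else tr.t_s[i],
                    "x_um": None if tr.centroid_um is None else tr.centroid_um[i, 0],
                    "y_um": None if tr.centroid_um is None else tr.centroid_um[i, 1],
                    "speed_um_s": None if tr.speed_um_s is None else tr.speed_um_s[i],
                    "motion_dir_rad": None if tr.motion_direction is None else tr.motion_direction[i],
                    "body_orient_rad": None if tr.body_orientation is None else tr.body_orientation[i],
                    "area_um2": tr.area_um2[i],
                    "aspect": tr.aspect[i],
                }
            )
    pd.DataFrame(rows, columns=TRACK_COLUMNS).to_csv(path, index=False, float_format="%.10g")


def read_tracks(path: str | Path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as e:
        raise ParseError(str(e)) from e
    _check_header(list(df.columns), TRACK_COLUMNS, path)
    return df


def write_schedule(schedule: StimulusSchedule, path: str | Path) -> None:
    payload = [
        {"t0": t0, "t1": t1, "leds": list(levels)} for t0, t1, levels in schedule.intervals
    ]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_schedule(path: str | Path) -> StimulusSchedule:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(e.msg, line=e.lineno) from e
    if not isinstance(payload, list):
        raise ParseError("schedule JSON must be a list of intervals")
    intervals = []
    for i, item in enumerate(payload):
        try:
            intervals.append((float(item["t0"]), float(item["t1"]), tuple(item["leds"])))
        except (KeyError, TypeError) as e:
            raise ParseError(f"interval {i} must have t0, t1, leds: {e}") from e
    return StimulusSchedule(intervals)


def write_events(events: list[GameEvent], path: str | Path) -> None:
    payload = [{"t": e.t_s, "kind": e.kind, "x": e.x, "y": e.y} for e in events]
    Path(path).write_text(json.dumps(payload, indent=2))


def read_events(path: str | Path) -> list[GameEvent]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise ParseError(e.msg, line=e.lineno) from e
    if not isinstance(payload, list):
        raise ParseError("event script JSON must be a list")
    events = []
    for i, item in enumerate(payload):
        try:
            kind = item["kind"]
            if kind not in ("tap_select", "shoot", "none"):
                raise ParseError(f"event {i}: unknown kind {kind!r}")
            events.append(
                GameEvent(
                    t_s=float(item["t"]),
                    kind=kind,
                    x=float(item.get("x", 0.0)),
                    y=float(item.get("y", 0.0)),
                )
            )
        except (KeyError, TypeError) as e:
            raise ParseError(f"event {i} must have t and kind: {e}") from e
    return events


def write_game_log(log: list[dict], path: str | Path) -> None:
    pd.DataFrame(log, columns=["t_s", "score", "ball_state", "goal_side"]).to_csv(
        path, index=False, float_format="%.10g"
    )
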
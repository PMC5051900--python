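"""Quantitative-inquiry applications: speed statistics, stimulus traces,
responsiveness scoring, and grid-search fitting of the motility model.

The statistics deliberately stop at mean, standard deviation, and standard
error of the mean with an SD-overlap verdict — the comparison rule the
companion instrument presents to students — rather than formal hypothesis
tests.

The responsiveness assay quantifies an originally qualitative 1–5 scale:
per 10-second stimulus interval, a population's *drift ratio* (net
displacement along the expected escape direction divided by path length)
and *immediacy* (mean heading alignment within the first seconds) map to a
score between 1 (nonmotile/spinning) and 5 (clear, immediate directional
response).  The cut points are this package's operationalization and are
configurable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from microswim.sim import (
    LightField,
    MotilityParams,
    SimTrack,
    StimulusSchedule,
    simulate_ensemble,
    wrap_angle,
)

__all__ = [
    "SpeedSummary",
    "TraceRecord",
    "ResponsivenessParams",
    "ResponsivenessResult",
    "FitResult",
    "summarize_speeds",
    "compare_conditions",
    "multiday_speed_table",
    "generate_multiday_speeds",
    "record_trace",
    "response_delay",
    "responsiveness_assay",
    "fit_motility",
    "track_speeds",
]


@dataclass(frozen=True)
class SpeedSummary:
    """Mean / SD / SEM of a set of speed measurements under one condition."""

    condition_label: str
    n: int
    mean_um_s: float
    sd_um_s: float
    sem_um_s: float
    sd_defined: bool = True  # False when n = 1 (sample SD undefined, reported as 0)


def summarize_speeds(speeds: Sequence[float], label: str = "") -> SpeedSummary:
    """Mean, sample SD (n−1), and SEM = SD/√n of a list of speeds (μm/s)."""
    speeds = np.asarray(list(speeds), dtype=float)
    if speeds.size == 0:
        raise ValueError("cannot summarize an empty speed list")
    n = speeds.size
    mean = float(np.mean(speeds))
    if n == 1:
        return SpeedSummary(label, 1, mean, 0.0, 0.0, sd_defined=False)
    sd = float(np.std(speeds, ddof=1))
    return SpeedSummary(label, n, mean, sd, sd / math.sqrt(n))


def compare_conditions(a: SpeedSummary, b: SpeedSummary) -> dict:
    """Compare two conditions by the SD-overlap rule.

    ``overlap`` is True iff |mean_a − mean_b| ≤ max(sd_a, sd_b): the means
    do not differ by more than the larger spread, so the data do not support
    a speed difference.  Requires n ≥ 2 in both groups.
    """
    if a.n < 2 or b.n < 2:
        raise ValueError("comparison requires n ≥ 2 in both conditions")
    diff = a.mean_um_s - b.mean_um_s
    return {
        "mean_diff_um_s": diff,
        "overlap": abs(diff) <= max(a.sd_um_s, b.sd_um_s),
    }


def track_speeds(track: SimTrack) -> np.ndarray:
    """Frame-to-frame speeds (μm/s) of a simulated track."""
    dt = np.diff(track.t_s)
    d = np.hypot(np.diff(track.x_um), np.diff(track.y_um))
    return d / dt


def multiday_speed_table(
    measurements: Sequence[tuple[str, int, Sequence[float]]],
) -> pd.DataFrame:
    """Per-culture, per-day speed summaries.

    ``measurements`` is a list of (culture_id, day, speeds); one output row
    per (culture, day) with n, mean, SD, SEM.
    """
    rows = []
    for culture, day, speeds in measurements:
        s = summarize_speeds(speeds, label=f"{culture}/day{day}")
        rows.append(
            {
                "culture_id": culture,
                "day": day,
                "n": s.n,
                "mean_um_s": s.mean_um_s,
                "sd_um_s": s.sd_um_s,
                "sem_um_s": s.sem_um_s,
            }
        )
    return pd.DataFrame(rows)


def generate_multiday_speeds(
    n_cultures: int = 4,
    n_days: int = 3,
    n_per_sample: int = 10,
    base_speed_um_s: float = 50.0,
    culture_sd: float = 10.0,
    within_sd: float = 12.0,
    seed: int | np.random.Generator = 0,
) -> list[tuple[str, int, list[float]]]:
    """Default measurement protocol: n = 10 speeds per culture per day.

    Each culture gets a persistent mean offset (between-culture variability)
    and each day an independent drift, emulating the large day-to-day
    variability of live cultures; individual cell speeds are drawn around
    the culture-day mean and clipped at 0.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = []
    for c in range(n_cultures):
        culture_mean = base_speed_um_s + rng.normal(0, culture_sd)
        for day in range(1, n_days + 1):
            day_mean = culture_mean + rng.normal(0, culture_sd / 2)
            speeds = np.clip(rng.normal(day_mean, within_sd, size=n_per_sample), 0, None)
            out.append((f"culture{c + 1}", day, speeds.tolist()))
    return out


@dataclass
class TraceRecord:
    """A single-cell trace split at one stimulus switch."""

    t_s: np.ndarray
    x_um: np.ndarray
    y_um: np.ndarray
    switch_time_s: float
    phase: np.ndarray = field(default=None)  # "pre"/"post" per sample

    def __post_init__(self) -> None:
        self.t_s = np.asarray(self.t_s, dtype=float)
        self.x_um = np.asarray(self.x_um, dtype=float)
        self.y_um = np.asarray(self.y_um, dtype=float)
        if self.phase is None:
            self.phase = np.where(self.t_s < self.switch_time_s, "pre", "post")

    def __len__(self) -> int:
        return len(self.t_s)


def record_trace(track: SimTrack, switch_time_s: float) -> TraceRecord:
    """Label a track's samples pre/post relative to a stimulus switch.

    Samples strictly before the switch are "pre"; the switch sample and
    everything after are "post".  The switch must fall within the track's
    time span.
    """
    if not (track.t_s[0] <= switch_time_s <= track.t_s[-1]):
        raise ValueError(
            f"switch time {switch_time_s} outside track span "
            f"[{track.t_s[0]}, {track.t_s[-1]}]"
        )
    return TraceRecord(track.t_s, track.x_um, track.y_um, switch_time_s)


def response_delay(
    trace: TraceRecord,
    new_preferred_dir: float,
    window_s: float = 1.0,
    tolerance_rad: float = math.pi / 4,
    min_hold_s: float = 2.0,
) -> float | None:
    """Time after the switch until the cell moves along the new direction.

    At each post-switch sample t, the motion direction over the window
    [t, t + window_s] is compared with ``new_preferred_dir``; the delay is
    the first t (minus the switch time) from which every subsequent window
    agrees within ``tolerance_rad``, provided that aligned stretch lasts at
    least ``min_hold_s`` — a transient chance alignment that the cell
    immediately abandons does not count as a response.  Returns None if the
    cell never durably aligns.
    """
    post = trace.t_s >= trace.switch_time_s
    if not post.any():
        raise ValueError("trace has no post-switch samples")
    idx = np.flatnonzero(post)
    aligned = []
    starts = []
    for i in idx:
        j = np.searchsorted(trace.t_s, trace.t_s[i] + window_s)
        j = min(j, len(trace.t_s) - 1)
        if j <= i:
            break
        dx = trace.x_um[j] - trace.x_um[i]
        dy = trace.y_um[j] - trace.y_um[i]
        if dx == 0 and dy == 0:
            aligned.append(False)
            starts.append(trace.t_s[i])
            continue
        direction = math.atan2(dy, dx)
        aligned.append(abs(wrap_angle(direction - new_preferred_dir)) <= tolerance_rad)
        starts.append(trace.t_s[i])
    if not aligned:
        return None
    aligned_arr = np.asarray(aligned)
    # first index from which alignment holds through the end of the trace
    misaligned = np.flatnonzero(~aligned_arr)
    first = 0 if misaligned.size == 0 else misaligned[-1] + 1
    if first >= len(aligned_arr):
        return None
    hold = starts[-1] - starts[first]
    max_possible = starts[-1] - starts[0]
    if hold + 1e-9 < min(min_hold_s, max_possible):
        return None
    return float(starts[first] - trace.switch_time_s)


@dataclass(frozen=True)
class ResponsivenessParams:
    """Cut points mapping drift/immediacy onto the 1–5 responsiveness scale."""

    nonmotile_speed_um_s: float = 5.0
    weak_drift: float = 0.2
    clear_drift: float = 0.5
    immediacy_window_s: float = 3.0
    immediacy_cos: float = 0.5


@dataclass
class ResponsivenessResult:
    interval_scores: list[int]
    interval_drift: list[float]
    interval_immediate: list[bool]
    interval_directions: list[float]
    mean_score: float
    sd_score: float


def _interval_score(
    positions: np.ndarray,  # (m, n, 2) samples for this interval
    t: np.ndarray,
    expected_dir: float,
    params: ResponsivenessParams,
) -> tuple[int, float, bool]:
    """Score one stimulus interval on the 1–5 scale."""
    disp = positions[-1] - positions[0]  # (n, 2) net displacement
    u = np.array([math.cos(expected_dir), math.sin(expected_dir)])
    along = disp @ u
    steps = np.diff(positions, axis=0)
    path_len = np.linalg.norm(steps, axis=2).sum(axis=0)
    duration = t[-1] - t[0]
    mean_speed = np.mean(path_len) / duration
    if mean_speed < params.nonmotile_speed_um_s:
        return 1, 0.0, False
    drift = float(np.mean(along) / max(np.mean(path_len), 1e-12))
    early = t - t[0] <= params.immediacy_window_s + 1e-9
    if early.sum() >= 2:
        estep = np.diff(positions[early], axis=0).reshape(-1, 2)
        norms = np.linalg.norm(estep, axis=1)
        ok = norms > 1e-12
        cosines = (estep[ok] @ u) / norms[ok]
        immediate = bool(cosines.size and np.mean(cosines) > params.immediacy_cos)
    else:
        immediate = False
    if drift < params.weak_drift:
        return 2, drift, immediate
    if drift < params.clear_drift:
        return 3, drift, immediate
    return (5 if immediate else 4), drift, immediate


def expected_directions(
    protocol: StimulusSchedule, taxis_sign: int = -1, field_: LightField | None = None
) -> list[float]:
    """Expected movement direction per protocol interval.

    For negative phototaxis the population should drift along the light
    propagation direction (away from the lit LED); for positive, against it.
    """
    field_ = field_ or LightField()
    dirs = []
    for t0, _, levels in protocol.intervals:
        L = field_.with_levels(levels).stimulus(np.zeros((1, 2)))[0]
        v = -taxis_sign * L
        if np.hypot(*v) < 1e-12:
            raise ValueError(f"interval at t={t0} has no net directional stimulus")
        dirs.append(float(math.atan2(v[1], v[0])))
    return dirs


def responsiveness_assay(
    positions_by_interval: Sequence[tuple[np.ndarray, np.ndarray]],
    protocol: StimulusSchedule | None = None,
    params: ResponsivenessParams = ResponsivenessParams(),
    taxis_sign: int = -1,
) -> ResponsivenessResult:
    """Score a population's light response on the 1–5 scale, per interval.

    ``positions_by_interval`` holds one (t, positions) pair per protocol
    interval with positions of shape (m, n, 2) — m time samples of n cells.
    The default protocol is the 8-direction sequence (L, R, U, D, R, D, L, U)
    at 10 s per interval.  The per-day score is the mean over intervals,
    with its SD.
    """
    protocol = protocol or StimulusSchedule.responsiveness_protocol()
    if len(positions_by_interval) != len(protocol.intervals):
        raise ValueError(
            f"got {len(positions_by_interval)} interval datasets for "
            f"{len(protocol.intervals)} protocol intervals"
        )
    dirs = expected_directions(protocol, taxis_sign)
    scores, drifts, immediates = [], [], []
    for (t, positions), expected in zip(positions_by_interval, dirs):
        positions = np.asarray(positions, dtype=float)
        if positions.ndim != 3 or positions.shape[0] < 2 or positions.shape[1] < 1:
            raise ValueError("each interval needs positions of shape (m ≥ 2, n ≥ 1, 2)")
        score, drift, immediate = _interval_score(positions, np.asarray(t), expected, params)
        scores.append(score)
        drifts.append(drift)
        immediates.append(immediate)
    return ResponsivenessResult(
        interval_scores=scores,
        interval_drift=drifts,
        interval_immediate=immediates,
        interval_directions=dirs,
        mean_score=float(np.mean(scores)),
        sd_score=float(np.std(scores, ddof=1)) if len(scores) > 1 else 0.0,
    )


def run_assay_simulation(
    params: MotilityParams,
    n_agents: int = 30,
    protocol: StimulusSchedule | None = None,
    dt: float = 0.1,
    seed: int | np.random.Generator = 0,
    field_: LightField | None = None,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Simulate a population through the assay protocol, split per interval."""
    protocol = protocol or StimulusSchedule.responsiveness_protocol()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    field_ = field_ or LightField()
    half = field_.half_side
    pos0 = rng.uniform(-half / 3, half / 3, size=(n_agents, 2))
    theta0 = rng.uniform(-math.pi, math.pi, size=n_agents)
    t, pos, _ = simulate_ensemble(pos0, theta0, params, protocol, dt, rng, field_)
    out = []
    for t0, t1, _levels in protocol.intervals:
        sel = (t >= t0 - 1e-9) & (t <= t1 + 1e-9)
        out.append((t[sel], pos[sel]))
    return out


# ---------------------------------------------------------------------------
# Motility model fitting


@dataclass
class FitResult:
    best: tuple[float, float, float]  # (v, k, Dr)
    discrepancy: float
    grid: pd.DataFrame  # columns v, k, Dr, discrepancy
    observed_summary: dict


_MSD_LAGS_S = (1.0, 3.0, 5.0)
_ALIGN_TIMES_S = (1.0, 3.0)


def _ensemble_summary(
    t: np.ndarray,
    pos: np.ndarray,  # (m, n, 2)
    schedule: StimulusSchedule,
    taxis_sign: int,
    field_: LightField,
) -> dict:
    """Summary statistics used as the fitting discrepancy basis.

    Mean path speed; ensemble MSD over the pre-switch (dark) phase at three
    lag times; mean alignment cos(motion direction − preferred direction)
    at two times after the final stimulus switch.
    """
    dt = t[1] - t[0]
    steps = np.diff(pos, axis=0)
    speed = float(np.mean(np.linalg.norm(steps, axis=2)) / dt)
    switch_t = schedule.intervals[-1][0]
    pre = t <= switch_t + 1e-9
    pre_pos = pos[pre]
    msd = []
    for lag in _MSD_LAGS_S:
        nlag = int(round(lag / dt))
        if nlag >= len(pre_pos):
            msd.append(float("nan"))
            continue
        d = pre_pos[nlag:] - pre_pos[:-nlag]
        msd.append(float(np.mean(np.sum(d**2, axis=2))))
    final_levels = schedule.intervals[-1][2]
    L = field_.with_levels(final_levels).stimulus(np.zeros((1, 2)))[0]
    pref = math.atan2(-taxis_sign * L[1], -taxis_sign * L[0])
    u = np.array([math.cos(pref), math.sin(pref)])
    align = []
    for ts in _ALIGN_TIMES_S:
        i = int(round((switch_t + ts) / dt))
        if i + 1 >= len(pos):
            align.append(float("nan"))
            continue
        step = pos[i + 1] - pos[i]
        norms = np.linalg.norm(step, axis=1)
        ok = norms > 1e-12
        align.append(float(np.mean((step[ok] @ u) / norms[ok])) if ok.any() else 0.0)
    return {"speed": speed, "msd": msd, "align": align}


def _discrepancy(sim: dict, obs: dict) -> float:
    """Weighted sum of squared summary differences (relative for speed/MSD,
    absolute for the bounded alignment terms)."""
    d = ((sim["speed"] - obs["speed"]) / max(obs["speed"], 1e-9)) ** 2
    for s, o in zip(sim["msd"], obs["msd"]):
        if math.isnan(o) or math.isnan(s):
            continue
        d += ((s - o) / max(abs(o), 1e-9)) ** 2
    for s, o in zip(sim["align"], obs["align"]):
        if math.isnan(o) or math.isnan(s):
            continue
        d += (s - o) ** 2
    return float(d)


def default_fit_schedule(dark_s: float = 10.0, lit_s: float = 10.0) -> StimulusSchedule:
    """Dark phase then a single Left LED: exposes v and Dr, then k."""
    return StimulusSchedule(
        [
            (0.0, dark_s, (0.0, 0.0, 0.0, 0.0)),
            (dark_s, dark_s + lit_s, (1.0, 0.0, 0.0, 0.0)),
        ]
    )


def simulate_fit_ensemble(
    params: MotilityParams,
    schedule: StimulusSchedule,
    n_rep: int,
    dt: float,
    rng: np.random.Generator,
    field_: LightField,
) -> tuple[np.ndarray, np.ndarray]:
    """n_rep agents started near the chamber center with random headings."""
    half = field_.half_side
    pos0 = rng.uniform(-half / 8, half / 8, size=(n_rep, 2))
    theta0 = rng.uniform(-math.pi, math.pi, size=n_rep)
    t, pos, _ = simulate_ensemble(pos0, theta0, params, schedule, dt, rng, field_)
    return t, pos


def fit_motility(
    observed: dict | tuple[np.ndarray, np.ndarray],
    grid: tuple[Sequence[float], Sequence[float], Sequence[float]],
    schedule: StimulusSchedule | None = None,
    n_rep: int = 50,
    seed: int = 0,
    dt: float = 0.1,
    taxis_sign: int = -1,
    field_: LightField | None = None,
) -> FitResult:
    """Grid-search fit of (v, k, Dr) to observed summary statistics.

    ``observed`` is either a precomputed summary dict (from
    :func:`_ensemble_summary`) or a raw (t, positions) ensemble, which must
    contain at least 10 time samples.  For every grid point, ``n_rep``
    replicate trajectories are simulated under ``schedule`` and their
    summary compared with the observation; the best point minimizes the
    discrepancy.  Deterministic given ``seed``.
    """
    vs, ks, drs = grid
    if not (len(vs) and len(ks) and len(drs)):
        raise ValueError("parameter grid must be non-empty")
    schedule = schedule or default_fit_schedule()
    field_ = field_ or LightField()
    if not isinstance(observed, dict):
        t_obs, pos_obs = observed
        if len(t_obs) < 10:
            raise ValueError("observed trace too short to fit (< 10 samples)")
        obs = _ensemble_summary(np.asarray(t_obs), np.asarray(pos_obs), schedule, taxis_sign, field_)
    else:
        obs = observed
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(vs) * len(ks) * len(drs))
    rows = []
    i = 0
    for v in vs:
        for k in ks:
            for dr in drs:
                rng = np.random.default_rng(children[i])
                i += 1
                p = MotilityParams(v, k, dr, taxis_sign)
                t, pos = simulate_fit_ensemble(p, schedule, n_rep, dt, rng, field_)
                sim = _ensemble_summary(t, pos, schedule, taxis_sign, field_)
                rows.append({"v": v, "k": k, "Dr": dr, "discrepancy": _discrepancy(sim, obs)})
    table = pd.DataFrame(rows)
    best_row = table.loc[table["discrepancy"].idxmin()]
    return FitResult(
        best=(float(best_row["v"]), float(best_row["k"]), float(best_row["Dr"])),
        discrepancy=float(best_row["discrepancy"]),
        grid=table,
        observed_summary=obs,
    )
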
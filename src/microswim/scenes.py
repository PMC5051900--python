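"""Benchmark scene generators with guaranteed ground-truth properties.

These build simulated populations for validating the imaging → tracking
pipeline.  The tracker is a nearest-neighbor follower with no identity
model, so recovery benchmarks require cells that never overlap; the
generator enforces that by construction (reject-and-redraw on minimum
pairwise trajectory distance).
"""

from __future__ import annotations

import numpy as np

from microswim.sim import AgentState, MotilityParams, SimTrack, StimulusSchedule, simulate

__all__ = ["separated_dark_tracks"]


def separated_dark_tracks(
    seed: int,
    n_agents: int = 10,
    duration_s: float = 10.0,
    dt: float = 0.1,
    speed_um_s: float = 50.0,
    rot_noise: float = 0.1,
    min_separation_um: float = 100.0,
    max_attempts: int = 50,
) -> tuple[list[SimTrack], np.random.Generator]:
    """A dark-chamber ensemble whose trajectories stay mutually separated.

    Agents start on a 5×2 grid spanning ±800 × ±400 μm (inside the default
    rendering field of view) with seed-drawn headings; candidate populations
    whose trajectories ever come closer than ``min_separation_um`` (about
    1.5 body lengths, enough to keep segmentation masks disjoint) are
    redrawn from the next child seed.  Returns the tracks and the generator
    for downstream use (e.g., rendering), deterministic given ``seed``.
    """
    if n_agents != 10:
        raise ValueError("the benchmark grid is defined for 10 agents")
    params = MotilityParams(speed_um_s=speed_um_s, turn_sensitivity=1.0, rot_noise=rot_noise)
    schedule = StimulusSchedule.constant((0, 0, 0, 0), duration_s)
    for attempt_seed in np.random.SeedSequence(seed).spawn(max_attempts):
        gen = np.random.default_rng(attempt_seed)
        population = []
        i = 0
        for y in (-400.0, 400.0):
            for x in np.linspace(-800.0, 800.0, 5):
                population.append(
                    AgentState((x, y), gen.uniform(-np.pi, np.pi), params, agent_id=i)
                )
                i += 1
        tracks = simulate(population, schedule, dt, seed=gen)
        pos = np.stack([tr.positions for tr in tracks], axis=1)  # (m, n, 2)
        diff = pos[:, :, None, :] - pos[:, None, :, :]
        dist = np.linalg.norm(diff, axis=-1)
        dist[:, np.arange(n_agents), np.arange(n_agents)] = np.inf
        if dist.min() >= min_separation_um:
            return tracks, gen
    raise RuntimeError(
        f"no non-overlapping population found in {max_attempts} attempts"
    )
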
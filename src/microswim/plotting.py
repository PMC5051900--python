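"""Plotting helpers for the inquiry apps and game overlays (matplotlib)."""

from __future__ import annotations

import numpy as np
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from microswim.inquiry import SpeedSummary, TraceRecord

__all__ = ["plot_speed_comparison", "plot_trace", "plot_game_overlay"]


def plot_speed_comparison(summaries: list[SpeedSummary], path=None, ax=None):
    """Bar chart of condition means with SD error bars (and SEM caps)."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    labels = [s.condition_label for s in summaries]
    means = [s.mean_um_s for s in summaries]
    sds = [s.sd_um_s for s in summaries]
    sems = [s.sem_um_s for s in summaries]
    x = np.arange(len(summaries))
    ax.bar(x, means, yerr=sds, capsize=6, color="#7fbf7f", label="mean ± SD")
    ax.errorbar(x, means, yerr=sems, fmt="none", ecolor="k", capsize=3, label="SEM")
    ax.set_xticks(x, labels)
    ax.set_ylabel("speed (μm/s)")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_trace(trace: TraceRecord, path=None, ax=None):
    """Two-phase swimming trace: pre-switch in blue, post-switch in green."""
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    pre = trace.phase == "pre"
    ax.plot(trace.x_um[pre], trace.y_um[pre], color="tab:blue", label="before switch")
    ax.plot(trace.x_um[~pre], trace.y_um[~pre], color="tab:green", label="after switch")
    ax.set_xlabel("x (μm)")
    ax.set_ylabel("y (μm)")
    ax.set_aspect("equal")
    ax.legend(frameon=False, fontsize=8)
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax


def plot_game_overlay(frame: np.ndarray, roi_center=None, roi_radius=40.0,
                      trail=None, ball=None, goal_rect=None, path=None, ax=None):
    """Game-style overlay: ROI circle, trail, ball, and goal on a frame."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4.5))
    ax.imshow(frame)
    if roi_center is not None:
        ax.add_patch(plt.Circle(roi_center, roi_radius, fill=False, color="red", lw=1.5))
    if trail is not None:
        trail = np.asarray(trail)
        ax.plot(trail[:, 0], trail[:, 1], "y-", lw=1)
    if ball is not None:
        ax.add_patch(plt.Circle(ball, 8, color="white", ec="k"))
    if goal_rect is not None:
        x0, y0, x1, y1 = goal_rect
        ax.add_patch(plt.Rectangle((x0, y0), x1 - x0, y1 - y0, fill=False, color="orange", lw=2))
    ax.set_axis_off()
    if path is not None:
        ax.figure.savefig(path, bbox_inches="tight", dpi=150)
        plt.close(ax.figure)
    return ax
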
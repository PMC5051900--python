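# Methods

## Phototaxis model

Swimmers are modeled as 2D active Brownian particles with a light-coupled
torque.  State is position (x, y) in μm and heading θ ∈ (−π, π], advanced
by Euler–Maruyama with default dt = 0.1 s:

    θ ← θ + k·I·sin(φ* − θ)·dt + √(2·D_r·dt)·η,   η ~ N(0, 1)
    x ← x + v·cosθ·dt,   y ← y + v·sinθ·dt

The four LEDs sit on the chamber edges (labels Left/Right/Up/Down name the
edge) and are treated as collimated beams: the net stimulus
**L** = Σⱼ ℓⱼ**u**ⱼ is position-independent, with **u**ⱼ the inward
propagation direction and ℓⱼ ∈ [0, 1] the drive level.  I = |**L**| and
φ* is the propagation direction of **L** for a negatively phototactic cell
(taxis sign −1, Euglena-like: it swims *away* from lit sources, i.e.
*with* the beam), or its opposite for a positive one (Volvox-like).  The
sin(φ* − θ) form is the simplest smooth taxis law consistent with the
three named motility parameters; its small-angle limit is a linear
restoring torque, and it vanishes at the unstable anti-aligned fixed
point.  An optional inverse-distance mode attenuates each LED from its
edge midpoint; it is off by default because the LEDs are far compared with
the 6.5 mm chamber.

Walls reflect: the overshooting coordinate is mirrored about the wall and
the heading is reflected about the wall normal (θ → π − θ at vertical
walls, θ → −θ at horizontal ones).  This keeps cells in the arena like the
physical chamber does; it is applied per axis, so corners compose two
reflections.

Assumptions deliberately made: 2D motion (the real chamber is 170 μm deep
— depth is ignored), taxis torque linear in intensity, no
low-intensity-positive/high-intensity-negative switching, no
photo-adaptation, no cell–cell interactions, no helical body wobble.

In the dark the model is an active Brownian particle with

    MSD(t) = (2v²/D_r²)·(D_r·t − 1 + e^(−D_r·t)),

used as an analytic check (n = 500 cells, 30 s, lags 1/5/20 s, agents
started at the center so walls are never reached; Euler discretization at
dt = 0.1 s introduces a relative bias of order D_r·dt ≈ 2%, inside the
10% check tolerance).

### Parameters

| parameter | units | default | why |
| --- | --- | --- | --- |
| v (speed) | μm/s | 50 | mid-range for a ~50–80 μm Euglena swimming ~1 body length/s |
| k (turning sensitivity) | rad/s per unit I | 1.0 | realigns in ~2 s at full drive, matching a visibly-within-seconds response |
| D_r (rotational noise) | rad²/s | 0.3 | persistence time ~3 s → visibly meandering paths |
| taxis sign | — | −1 | Euglena flees bright directional light; +1 models Volvox |
| chamber side | μm | 6500 | physical chamber geometry |
| dt | s | 0.1 | matches 10 fps video; halving dt changes dark-MSD by <1% |

A single seeded generator drives a whole simulation; the seed is recorded
in run metadata, and all population simulation is vectorized over agents
(one RNG stream, so results are reproducible but not agent-order
invariant).

## Synthetic imaging

The renderer emulates the transmitted-light camera view: uniform bright
gray background (level 220), cells as filled ellipses in a green-dominant
color (RGB 30/140/30) with major axis equal to body length (drawn
uniformly from 50–80 μm per cell, width 8–15 μm) oriented along the
heading.  Rasterization is 4× supersampled, so sub-pixel positions shift
pixel coverage continuously; optional Gaussian pixel noise is added last.
Default optics: 2 μm/px, 640×480 px (1.28 × 0.96 mm window centered in the
chamber), 10 fps; recovery benchmarks use a 1280×960 window so 10 cells
fit with room to wander.  Image rows grow downward while chamber y grows
upward; all exported kinematics are converted to the chamber frame.

Not emulated: the optical PSF, defocus and refocusing, flagella, shading
gradients, compression artifacts, or colorless/rolling cells.  Passing the
round-trip benchmarks therefore shows the pipeline is *self-consistent*
and correctly calibrated (scale, axes, timing), not that it is robust to
every artifact of real video.

## Recognition and tracking

Segmentation: a pixel is foreground iff G ≥ 60 **and** G − max(R, B) ≥ 20
(8-bit).  The margin term makes the rule robust to overall brightness; the
printed description of the original software names only "green pixel
values", so the two thresholds are this package's choice.  Raising the
margin can only shrink the mask (tested property).

Detection: 8-connected components; each component's centroid and moment
ellipse come from the pixel-coordinate covariance (with the +1/12
per-pixel variance term, exact for filled ellipses; full axes = 4√λ).
Components are kept if area lies in a range derived from the nominal
cell-size range (50–80 μm × 8–15 μm ellipse area, padded ±30% →
~154–1593 μm²) and moment aspect ratio ≥ 1.5 ("elongated").

Tracking: nearest-neighbor binding within a circular ROI (default radius
40 px) from a user/seed point; ties break toward larger area, then lower
index.  After 5 consecutive missed frames a track is marked lost and
truncated at the last hit.  No motion model: at 10 fps a 50 μm/s cell
moves ~2.5 px/frame, far inside the ROI.  Consequently crossing cells can
swap identities; the benchmark scene generator (`microswim.scenes`)
enforces ≥100 μm pairwise trajectory separation by reject-and-redraw, as
the recovery benchmarks are defined for non-overlapping cells.

Kinematics: centroids are smoothed by a centered moving average (default
5 frames, shrinking symmetrically at the ends), speed is the centered
finite difference of the smoothed centroid × pixel scale × fps, and the
body-axis π-ambiguity is resolved toward the motion direction where speed
exceeds 5 μm/s.  Smoothing a curving path biases speed slightly downward
(≈2% at D_r = 0.2, window 0.5 s), which is inside the 5% recovery check.

## Games

Both engines are headless, frame-driven, and deterministic under replay.
Soccer: 5 points per goal, −1 per tap-select, goal side toggles at every
30 s boundary — these three constants are the game's fixed rules; pickup
radius (30 px), shoot distance (300 px), ball lead (25 px), and goal
geometry are not part of the rules and are configurable defaults chosen
to make scripted replays behave like live gameplay.  A shot resolves
instantaneously: it scores iff the segment of length shoot-distance along
the motion direction crosses the goal rectangle (slab clipping, verified
against an independent geometric oracle); otherwise the ball lands free at
the segment end.  After a goal the ball resets to the field center.  The
score identity 5·goals − 1·taps holds after any event script (tested
property; the score may go negative).  Maze: waypoints must be collected
in order within a 20 px capture radius; the post-game report gives the
mean minimum distance from the recorded trace to the designated polyline
(shapely; dense-sampling brute force as the test oracle).

## Inquiry statistics

Speed summaries report mean, sample SD (n−1; flagged undefined and
reported as 0 when n = 1) and SEM = SD/√n.  Condition comparison uses the
deliberately informal SD-overlap rule — |Δmean| ≤ max(SD_a, SD_b) — and no
p-values, mirroring the instrument's pedagogical statistics.  The
multi-day protocol generator emits n = 10 speeds per culture per day
(default 4 cultures × 3 days) with persistent per-culture offsets
(SD 10 μm/s), day-to-day drift (SD 5 μm/s), and within-sample spread
(SD 12 μm/s) around 50 μm/s — magnitudes chosen to produce the large
day-to-day variability live cultures show, clipped at 0.

Response delay: at each post-switch time the motion direction over a
forward window (default 1 s) is compared with the new preferred direction;
the delay is the first time from which every subsequent window stays
within π/4, with the aligned stretch required to last ≥ 2 s.  The
persistence requirement is what separates a phototactic response from
chance alignment: an insensitive random walker (k = 0, D_r = 0.3) shows a
durable-alignment rate of only ~10% per 10 s trace, while a transient
"first window hit" definition would fire ~75% of the time.

Responsiveness assay: the qualitative 1–5 scale is operationalized per
10 s interval from two population statistics — drift ratio (mean net
displacement along the expected escape direction ÷ mean path length,
bounded in [−1, 1]) and immediacy (mean step-direction cosine > 0.5 within
the first 3 s).  Mapping: mean speed < 5 μm/s → 1 (nonmotile); drift
< 0.2 → 2; < 0.5 → 3; ≥ 0.5 without immediacy → 4; with immediacy → 5.
All cut points (0.2, 0.5, 3 s, 5 μm/s) are this package's
operationalization of a by-eye scale and are configurable.  On simulated
populations the mapping is monotone in k: k = 0 scores 2, k ≈ 0.5 scores
3–4, k ≥ 1 scores 4–5.

Model fitting replaces by-eye "visual fitting" with an explicit grid
search.  Summary statistics: mean path speed; dark-phase ensemble MSD at
lags 1/3/5 s; mean step alignment with the preferred direction 1 s and 3 s
after the stimulus switch.  Discrepancy is a sum of squared differences,
relative for speed and MSD and absolute for the bounded alignment terms.
The default stimulus program is 10 s dark then 10 s single-LED — the dark
phase identifies v and D_r, the lit phase k.  Each grid point simulates
n_rep replicates (default 50) from a child seed of the master seed, so the
whole fit is deterministic.  Benchmarks: a 5×5×5 grid bracketing
(v, k, D_r) = (50, 1.0, 0.3) recovers the truth within one grid cell in
20/20 seeded repeats (observation: 100 cells under the same program).

## Problem sizes and determinism

Default check sizes were chosen so the full suite runs in about a minute:
MSD ensemble n = 500 × 300 steps; oracle comparisons 100 randomized
instances per primitive; round trip 10 cells × 101 frames at 1280×960;
fit recovery 20 repeats × 125 grid points × 50 replicates.  Every
stochastic quantity is seeded; hypothesis-based property tests run
derandomized.

## Known limitations

- No occlusion or identity reasoning in the tracker; crossing cells swap.
- The taxis law and its linear intensity dependence are modeling choices
  made here; other smooth alignment laws would fit the same three
  parameters.
- No low-intensity attraction for Euglena (the instrument exercises only
  the high-intensity repulsion regime).
- The Volvox-like positive-taxis mode shares the Euglena body model;
  rendering and shape filters are not adapted to spherical colonies.
- Responsiveness scores and the SD-overlap verdict are pedagogical
  statistics, not inferential tests.
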
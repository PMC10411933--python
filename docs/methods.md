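# Methods

`aimkin` simulates and analyzes center-out aiming movements of the kind
performed in first-person-shooter (FPS) aim training: a player uses a mouse
or trackpad to move a cursor from a start point onto a circular target and
click it. Movements are made in one of two visual contexts — **Point**
(deltas translate the cursor over a static scene) and **Look** (deltas
pan/tilt a first-person camera while the cursor stays at screen center).
This note describes the task model, the synthetic performer, the
segmentation and metric algorithms, the numerical choices behind them, and
what the package's tests do and do not establish about real data.

## Workspace and context equating

All analysis happens in plane coordinates: origin at the center of a 3-au
target plane inside a 4-au-tall scene, x rightward, y upward, angles
counterclockwise from +x ("au" are arbitrary Unity-style units). The two
contexts are equated *constructively*: a single virtual cursor in plane
coordinates is driven by gain-scaled device deltas, Point renders it
directly, and Look renders the camera pose whose central ray meets the plane
at the cursor (`yaw = arctan(x/d)`, `pitch = arctan(y/d)` with `d` the
camera-to-plane distance; the default `d = 2/tan(30°) ≈ 3.46` au makes the
scene height fill a 60° vertical field of view). Identical delta streams
therefore produce bitwise-identical analysis-space trajectories in both
contexts; the context label only matters for rendering and for the
performer's latency penalties. This guarantees the equated-movement property
exactly, at the price of not modeling second-order screen-motion detail
(e.g. perspective distortion of the background during large pans), which the
analysis never uses.

During the pre-trial homing phase the cursor snaps to the start point when
within 0.05 au of it; the boundary is inclusive (distance = 0.05 snaps).

## Task engine

**Staircased block.** 320 trials per context, organized as 40 cycles in
which the eight target angles (0–315° in 45° steps, radius 1 au) each appear
once in a fresh random permutation. The shot time limit follows two
interleaved one-up/one-down staircases starting at 300 and 1,500 ms with a
constant 30 ms step: success lowers the tested staircase's limit, failure
raises it, which drives the limit toward the player's ~50%-success
threshold. Staircase assignment uses balanced random pairs — each
consecutive trial pair contains both staircases in random order — so the
tested staircase switches after most trials, never repeats more than twice,
and both get exactly 160 trials. A limit that would reach zero is clamped at
one step and flagged (unreachable in practice). The **asymptotic time
limit**, the block's skill measure, is the median of the per-trial limits
over the last 40 trials of each staircase pooled (80 values); a
`per_staircase=False` mode pools the last 40 trials of the block instead.

**Aim-trainer session.** 20 rounds of 48 chained targets. Each round is two
cycles; within a cycle each of the 24 combinations of distance
{0.4, 0.6, 0.8} au and angle {0–315°, 45° steps} occurs once, applied as a
displacement from the previous target (the round's first target displaces
from the plane center). Because every angle carries all three distances, a
cycle's displacement vectors sum to zero: each cycle is a closed loop that
starts and ends at the plane center. Rounds are generated by rejection
sampling — shuffle a cycle's combos, chain the positions, restart on any
position farther than 1 au from the center. The closed-loop structure makes
cycles independent, so the sampler restarts per cycle; this is
distributionally identical to restarting whole rounds and exponentially
cheaper (per-cycle acceptance is roughly 1 in 10³; a round generates in
~15 ms).

## The synthetic performer

The generator stands in for the deposited human data and is intentionally
the simplest process that reproduces the qualitative structure the analysis
must detect. It is not a claim about how people actually generate movements.

A trial unfolds as:

1. **Reaction time**: shifted lognormal, `rt_location + rt_scale·exp(σZ)`
   (defaults 180 ms + 60 ms median, σ = 0.35), plus a 25 ms additive penalty
   in the Look context.
2. **Primary movement**: one minimum-jerk, rest-to-rest reach
   `s(τ) = D(10τ³ − 15τ⁴ + 6τ⁵)` toward a noisy aimpoint. Duration is
   `T = a + b·D` (defaults a = 120 ms, b = 280 ms/au), giving the classic
   peak speed `1.875·D_aim/T` at mid-movement and strictly
   distance-increasing speed profiles. The aimed extent is
   `N(0.88·D, (0.12·D)²)` — a mean undershoot with signal-dependent noise —
   and the direction deviates by `N(0, 3°)` plus an optional per-angle bias
   table (zero by default: the systematic bias curve seen in human data is
   not built in). Extent SD exceeding the implied tangential SD is enforced
   at construction, so endpoint clouds are elongated along the movement axis
   (default aspect ratio ≈ 2.4–2.5 at every distance).
3. **Corrections**: while the cursor is outside the target, after a
   correction latency (150 ms, +24 ms in Look) a corrective minimum-jerk
   submovement covers 85% of the remaining vector error with the same
   proportional extent/direction noise. A cap (12 submovements) bounds
   non-convergent loops; hitting it records a failure.
4. **Click dwell**: shifted lognormal (80 ms + 70 ms median, σ = 0.5); the
   click lands on the next frame boundary. Success requires the click inside
   the target and, when a time limit applies, at or before it.

Practice improvement in the aim-trainer session is dual-rate: latencies and
noise scales are multiplied by
`m(k) = (1 − A_f − A_s) + A_f·e^(−0.7k) + A_s·e^(−0.05k)` per round `k`
(A_f = 0.25, A_s = 0.20), movement durations by a slow-only analogue
(amplitude 0.12) — fast early gains followed by sustained slow improvement,
with all phases improving concurrently.

Trials are built as continuous piecewise trajectories (stationary +
minimum-jerk segments) and then sampled at the frame rate (default 60 Hz),
so the emitted device deltas reconstruct the logged cursor positions to
float precision and ground truth can be computed analytically.

**Ground-truth labels.** Each simulated trial can carry phase labels for
validating the segmenter. The labels use the segmenter's own convention:
onset and primary end are the *analytic* times the minimum-jerk radial speed
crosses 0.5 au/s (closed form on the quintic), and last target entry is the
root-refined time the continuous path last crosses the target boundary
before the click. Recovery tests therefore measure the estimator's
discretization error, not disagreement about where a phase "really" begins;
with σ = 0 everywhere the performer is fully deterministic and serves as the
segmentation oracle.

**What the generator does not emulate.** Hand paths are straighter than
human ones (linearity index ≈ 0.02 vs ≈ 0.08 for players: there is no
within-movement curvature, only initial-direction error); frame-time jitter,
device-specific dynamics, anticipatory clicking, and fatigue are absent; and
with purely proportional extent noise the effective index of difficulty is
nearly constant across the three distances (W_e ∝ D_e), so a Fitts
regression over distance cells is ill-conditioned on synthetic sessions —
the movement-time/ID relationship over a proper ID range is instead
exercised by exact-recovery fixtures. Passing tests show the *pipeline*
recovers what the generator put in; they do not certify performance on the
messier human recordings.

## Segmentation

Successful trials decompose into four phases whose durations sum exactly to
the acquire time (target shown → successful click):

- **Onset**: first sample after target onset with radial speed
  (d|cursor − start|/dt) above 0.5 au/s; never crossing flags a no-movement
  trial. Higher thresholds never yield earlier onsets.
- **Primary end**: after the post-onset peak of tangential speed, the
  earliest sample that is either a local minimum below 50% of the peak or
  below the 0.5 au/s threshold, whichever comes first; failing both before
  the click, the click time. Both constants are configurable; this is a
  deliberately concrete instantiation of speed-profile discontinuity
  parsing, and no sigmoid submovement model is fit.
- **Last entry**: the start of the boundary-inclusive target-occupancy
  interval containing the click. A successful click outside every entry
  interval raises a data-inconsistency error.
- Phase durations: reaction (shown→onset), primary movement (onset→primary
  end), correction (primary end→last entry, clamped to 0 when the primary
  movement itself enters the target), dwell (from the later of last
  entry/primary end to the click). The stored acquire time is the sum of the
  four durations, which makes the decomposition identity bit-exact; it
  telescopes to click − shown up to float rounding (< 1e-9 ms).

Numerics: speeds come from central finite differences at interior samples,
upgraded to the fourth-order five-point stencil when sampling is uniform
(second-order at the edges and for irregular timestamps). The higher-order
interior stencil matters: the O(dt²) bias of plain central differences
(~0.016 au/s on a 60 Hz minimum-jerk profile) is enough to displace a
threshold crossing by one full sample when the true crossing falls within a
millisecond of a frame. An optional centered moving average (odd width) can
be applied to the speeds only; the default is off, because simulated traces
are already band-limited and smoothing adds a curvature-induced lag of up to
a frame at the down-crossing. With these defaults, every recovered boundary
on noiseless trials lies within one frame period (16.7 ms at 60 Hz) of the
analytic label. Segmentation reads only the analysis-space path, so it is
invariant to the trial's context flag.

## Metrics

Per trial, at the detected primary end: radial extent |cursor − start|,
hand angle (signed, counterclockwise-positive deviation from the
start→target direction), and the endpoint rotated into a target-aligned
frame (target direction mapped to +y, so y is the on-axis/extent coordinate
and x the off-axis/direction coordinate). Peak speed is the maximum *radial*
speed between onset and click. Note the extent is measured where the speed
criterion ends the movement — slightly short of the physical stop (≲1% of
D) — matching how such measures are extracted from thresholded profiles.

- **Linearity index**: max perpendicular deviation from the straight
  start→target segment divided by its length (0 for straight; 0.5 for a
  semicircular arc). A path-length-ratio alternative was considered and
  rejected to keep the index bounded and rotation-invariant in the same
  units; the chosen form is the package's definition.
- **Error ellipse**: eigendecomposition of the aligned-endpoint sample
  covariance; semi-axis k = √(q·λ_k) with q the χ²(2 df) quantile at the
  coverage (5.991 at 95%); aspect ratio √(λ_major/λ_minor). Rank-deficient
  covariance raises an error reporting the rank. The aspect estimator's
  single-cloud sampling SD at n = 500 is ~4.5%, so calibration checks
  average over independent clouds.
- **Effective index of difficulty**: `ID_e = log2(D_e/W_e + 1)` with
  `W_e = 4.133 × SD` of the signed on-axis endpoint coordinate and `D_e` the
  cell's mean extent; the on-axis projection (rather than 2D scatter) is
  used, and zero spread yields NaN. Movement time regresses on ID_e by
  ordinary least squares.
- **Directional bias**: per-participant median hand angle per target angle,
  then the group mean.
- **Summaries**: the staircased-block summary uses only successful trials
  from the last 40 trials of each staircase per context (≤80 trials) —
  medians of the temporal phases, mean/SD of extent, mean peak speed, SD of
  hand angle, plus the asymptotic limit; aim-trainer variants summarize per
  round (learning curves; the correction phase is reported as mean as well
  as median, since movements that enter the target during the primary reach
  contribute zero correction and dominate the median at short distances)
  and per distance cell (Fitts, ellipses, speed scaling).

## Screening

Three annotation-only checks mirror the task's data-quality rules, all with
strict boundary comparisons: frame rate (fail below 30 fps in any context,
or a between-context difference above 10 fps; in the aim-trainer variant a
first-to-last-round drop above 10 fps), stabilization (last-window success
rate more than 10 percentage points from the intended 50%), and robust
outliers (|x − median| > 3 × 1.4826 × MAD; when the MAD is zero, any value
off the median is flagged — the robust-z limit). The outlier mask is
invariant to affine transforms of its input.

## Files, configuration, determinism

Sessions serialize to a versioned plain tab-separated text format (header
JSON line + `[trials]`, `[samples]`, `[events]`, optional `[ground_truth]`
sections) with full-precision floats; reading validates time ordering,
delta/position consistency (1e-9 au), orphan rows, and click-inside-target
for successes, citing the offending line. Parsing uses round-trip float
precision so write→read is lossless and byte-deterministic for a fixed seed.
A YAML config fully determines scene geometry, performer parameters,
segmentation constants and screening thresholds; the defaults reproduce the
task constants (0.5 au/s, 30 ms, 300/1,500 ms, 0.4/0.6/0.8 au, 45° grid,
1 au cap, 95% coverage, 3 MADs, 1.4826, 30/10 fps). All randomness flows
from one seeded NumPy generator. An adapter for the study's deposited raw
data would plug in at `aimkin.sessions` (mapping the deposit's schema onto
`TrialRecord`); it is not implemented here.

## Problem sizes used in tests and scripts

Chosen as the package's own desk-scale conditions: staircase convergence
averages 100 seeded 320-trial blocks; segmentation recovery uses 1,000
noiseless trials over four distances and eight directions; ellipse
calibration uses 40 clouds of n = 500 per aspect ratio; the analysis scripts
simulate a cohort of 8 synthetic participants (full 640-trial and 960-
movement sessions each) with mild between-subject parameter jitter and a
mouse/trackpad split. End to end, the test suite runs in well under a
minute and each analysis script in seconds.

## Known limitations

Beyond the generator gaps above: the correction model is discrete and
target-directed (no online trajectory blending), the Look context's extra
visual-motion consequences are represented only as additive latency
penalties, unsuccessful trials yield partial segmentations only, and the
group-level inferential statistics of a real study (t-tests, ANOVAs, mixed
models) are deliberately out of scope — the package exports tidy tables for
standard statistical tooling instead.
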
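"""Synthetic performer: generates mouse traces with the statistical
structure of human center-out shooting movements.

The generator is deliberately simple — a shifted-lognormal reaction time, a
minimum-jerk primary movement whose duration grows linearly with distance,
signal-dependent extent noise (SD proportional to distance) with smaller
directional noise (endpoint clouds elongated along the movement axis),
iterative multiplicative corrective submovements, a lognormal click dwell,
small additive Look-context penalties on reaction and correction latency,
and dual-rate (fast-then-slow) multiplicative improvement across practice
rounds.  It is a data generator for validating the analysis pipeline, not a
model of the participants' true generative process.

Every trial is built as a continuous piecewise trajectory (stationary and
minimum-jerk segments), then sampled at the frame rate, so the emitted
device deltas are exactly consistent with the logged cursor positions and
ground-truth phase boundaries can be computed analytically.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
from scipy.optimize import brentq

from .contexts import SceneConfig
from .records import GroundTruth, Session, TrialRecord
from .task import (
    ANGLES_DEG,
    EXP2_DISTANCES,
    STAIRCASE_STARTS_MS,
    StaircaseState,
    TrialSpec,
    exp1_block,
    exp2_session,
    staircase_update,
)

__all__ = [
    "PerformerParams",
    "min_jerk_profile",
    "simulate_trial",
    "simulate_experiment1",
    "simulate_experiment2",
    "learning_multipliers",
]

#: Radial-speed threshold (au/s) shared with the segmentation stage; used
#: here only to express ground-truth labels in the segmenter's convention.
ONSET_THRESHOLD_AU_S = 0.5


@dataclass(frozen=True)
class PerformerParams:
    """Generative parameters of the synthetic mover.

    Latency draws are shifted lognormals: ``location`` is the shift (ms),
    ``scale`` the median of the lognormal part (ms) and ``sigma`` its
    log-space SD (dimensionless); sigma = 0 makes the draw deterministic at
    location + scale.  Primary-movement duration is ``mt_intercept +
    mt_slope * D`` ms for a D-au movement.  Extent noise is
    signal-dependent (SD = extent_cv * D au) and, with the default
    direction noise, gives endpoint ellipses elongated along the movement
    axis with aspect ratio near 2.3 at every distance.
    """

    rt_location: float = 180.0      # ms, reaction-time shift
    rt_scale: float = 60.0          # ms, reaction-time lognormal median
    rt_sigma: float = 0.35          # log-space SD of reaction time
    mt_intercept: float = 120.0     # ms
    mt_slope: float = 280.0         # ms per au
    extent_cv: float = 0.12         # SD of primary extent as fraction of D
    angle_sd: float = 3.0           # deg, direction noise at primary end
    undershoot_frac: float = 0.88   # mean primary extent as fraction of D
    corr_latency: float = 150.0     # ms between submovements
    corr_gain: float = 0.85         # fraction of remaining error per correction
    dwell_location: float = 80.0    # ms, click-dwell shift
    dwell_scale: float = 70.0       # ms, click-dwell lognormal median
    dwell_sigma: float = 0.5        # log-space SD of click dwell
    look_rt_penalty: float = 25.0   # ms added to reaction time in Look
    look_corr_penalty: float = 24.0  # ms added to each correction latency in Look
    learn_fast: float = 0.7         # per-round fast improvement rate
    learn_slow: float = 0.05        # per-round slow improvement rate
    learn_fast_amp: float = 0.25    # amplitude of the fast process
    learn_slow_amp: float = 0.20    # amplitude of the slow process
    learn_mt_amp: float = 0.12      # slow-only amplitude on movement duration
    frame_rate: float = 60.0        # Hz
    max_submovements: int = 12      # numerical guard on the correction loop
    angle_bias: tuple[tuple[float, float], ...] | None = None  # (angle, bias deg)

    def __post_init__(self) -> None:
        if not 0 < self.corr_gain <= 1:
            raise ValueError("corr_gain must be in (0, 1]")
        if self.frame_rate < 30:
            raise ValueError("frame_rate must be >= 30 Hz")
        if not 0 < self.undershoot_frac <= 1.2:
            raise ValueError("undershoot_frac out of range")
        # elongated-along-axis endpoints: extent SD must exceed the
        # tangential SD implied by the direction noise (both scale with D,
        # so one check covers all distances)
        if self.angle_sd > 0:
            tangential_cv = self.undershoot_frac * math.tan(math.radians(self.angle_sd))
            if self.extent_cv <= tangential_cv:
                raise ValueError(
                    "extent_cv must exceed the tangential spread implied by "
                    f"angle_sd ({self.extent_cv} <= {tangential_cv:.4f})"
                )

    def bias_for(self, angle_deg: float) -> float:
        if not self.angle_bias:
            return 0.0
        for ang, bias in self.angle_bias:
            if math.isclose(ang % 360.0, angle_deg % 360.0):
                return bias
        return 0.0

    def noiseless(self, **overrides) -> "PerformerParams":
        """Deterministic variant: all stochastic draws collapse to their
        central values (used as the segmentation oracle)."""
        return replace(
            self, rt_sigma=0.0, dwell_sigma=0.0, extent_cv=0.0, angle_sd=0.0, **overrides
        )

    @property
    def frame_dt(self) -> float:
        return 1000.0 / self.frame_rate

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        if d["angle_bias"] is not None:
            d["angle_bias"] = [list(pair) for pair in d["angle_bias"]]
        return d


# ---------------------------------------------------------------------------
# minimum-jerk kernel

def _mj_s(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk displacement, s(0)=0, s(1)=1."""
    return 10 * tau**3 - 15 * tau**4 + 6 * tau**5


def _mj_v(tau: np.ndarray) -> np.ndarray:
    """Normalized minimum-jerk speed ds/dtau; peak 1.875 at tau = 0.5."""
    return 30 * tau**2 - 60 * tau**3 + 30 * tau**4


def min_jerk_profile(D: float, T_ms: float, dt_ms: float):
    """Sampled minimum-jerk displacement (au) and speed (au/s) for a
    rest-to-rest movement of amplitude ``D`` and duration ``T_ms``.

    Returns ``(t_ms, s, v)``; the speed is the analytic derivative, with
    peak 1.875 * D / T at mid-movement.
    """
    if not (D > 0 and T_ms > 0 and dt_ms > 0):
        raise ValueError("D, T and dt must all be positive")
    t = np.arange(0.0, T_ms + dt_ms / 2, dt_ms)
    tau = np.clip(t / T_ms, 0.0, 1.0)
    s = D * _mj_s(tau)
    v = (D / (T_ms / 1000.0)) * _mj_v(tau)
    return t, s, v


def _threshold_crossings(amplitude: float, T_ms: float, v_thr: float = ONSET_THRESHOLD_AU_S):
    """Analytic times (ms from movement start) at which the minimum-jerk
    speed of a movement rises above / falls below ``v_thr`` au/s, or None
    if the peak never reaches the threshold."""
    T_s = T_ms / 1000.0
    q = math.sqrt(v_thr * T_s / (30.0 * amplitude)) if amplitude > 0 else float("inf")
    if 4 * q >= 1.0:
        return None
    root = math.sqrt(1.0 - 4.0 * q)
    return (0.5 * (1.0 - root) * T_ms, 0.5 * (1.0 + root) * T_ms)


# ---------------------------------------------------------------------------
# piecewise trajectory

class _Trajectory:
    """Contiguous stationary / minimum-jerk segments; position is defined
    for all t >= 0 (clamped to the final position beyond the last segment)."""

    def __init__(self) -> None:
        self._t0: list[float] = []
        self._t1: list[float] = []
        self._p0: list[np.ndarray] = []
        self._vec: list[np.ndarray] = []

    def add(self, t0: float, t1: float, p0, vec) -> None:
        if t1 <= t0:
            raise ValueError("segment must have positive duration")
        self._t0.append(t0)
        self._t1.append(t1)
        self._p0.append(np.asarray(p0, dtype=float))
        self._vec.append(np.asarray(vec, dtype=float))

    def pos(self, t) -> np.ndarray:
        t = np.atleast_1d(np.asarray(t, dtype=float))
        t0 = np.array(self._t0)
        t1 = np.array(self._t1)
        p0 = np.array(self._p0)
        vec = np.array(self._vec)
        idx = np.clip(np.searchsorted(t1, t, side="left"), 0, len(t1) - 1)
        tau = np.clip((t - t0[idx]) / (t1[idx] - t0[idx]), 0.0, 1.0)
        return p0[idx] + _mj_s(tau)[:, None] * vec[idx]

    def pos1(self, t: float) -> np.ndarray:
        return self.pos([t])[0]


def _last_entry_time(
    traj: _Trajectory, target: np.ndarray, radius: float, t_end: float, dt_dense: float = 0.25
) -> float | None:
    """Exact time of the last outside->inside boundary crossing before
    ``t_end`` (root-refined from a dense scan), or the first sample time if
    the trajectory starts inside."""

    def signed(t: float) -> float:
        p = traj.pos1(t)
        return math.hypot(p[0] - target[0], p[1] - target[1]) - radius

    ts = np.arange(0.0, t_end + dt_dense / 2, dt_dense)
    d = np.hypot(*(traj.pos(ts) - target).T) - radius
    inside = d <= 0
    if not inside[-1]:
        return None
    if inside.all():
        return 0.0
    k = int(np.nonzero(~inside)[0][-1])  # last outside sample
    return float(brentq(signed, ts[k], ts[k + 1], xtol=1e-9))


# ---------------------------------------------------------------------------
# single-trial simulation

def _lognormal(location: float, scale: float, sigma: float, rng: np.random.Generator) -> float:
    return location + scale * math.exp(sigma * rng.standard_normal()) if sigma > 0 else location + scale


_UNIT_MULTIPLIERS: Mapping[str, float] = {"latency": 1.0, "noise": 1.0, "mt": 1.0}


def learning_multipliers(round_index: int, params: PerformerParams) -> dict[str, float]:
    """Dual-rate practice multipliers for round ``round_index`` (0-based).

    Latency and noise parameters improve through a fast and a slow
    exponential process; movement duration improves through the slow
    process only.  All multipliers equal 1 at round 0.
    """
    k = float(round_index)
    fast = math.exp(-params.learn_fast * k)
    slow = math.exp(-params.learn_slow * k)
    m = (
        (1.0 - params.learn_fast_amp - params.learn_slow_amp)
        + params.learn_fast_amp * fast
        + params.learn_slow_amp * slow
    )
    m_mt = (1.0 - params.learn_mt_amp) + params.learn_mt_amp * slow
    return {"latency": m, "noise": m, "mt": m_mt}


def simulate_trial(
    params: PerformerParams,
    spec: TrialSpec,
    time_limit: float | None,
    rng: np.random.Generator,
    *,
    start=(0.0, 0.0),
    target=None,
    scene: SceneConfig | None = None,
    trial_id: int = 0,
    round_index: int | None = None,
    multipliers: Mapping[str, float] | None = None,
    with_ground_truth: bool = True,
) -> TrialRecord:
    """Simulate one shot attempt and return its :class:`TrialRecord`.

    The trial unfolds as: reaction latency (plus the Look penalty in the
    Look context) -> one minimum-jerk primary movement toward a noisy
    aimpoint -> corrective submovements (each after a correction latency,
    covering ``corr_gain`` of the remaining vector error with proportional
    noise) until the cursor is inside the target or the submovement cap is
    hit -> a click-dwell draw -> a click on the next frame boundary.  The
    outcome is success iff the click lands inside the target and, when a
    time limit is given, at or before it.
    """
    scene = scene or SceneConfig()
    mult = dict(_UNIT_MULTIPLIERS if multipliers is None else multipliers)
    start = np.asarray(start, dtype=float)
    target = np.asarray(
        spec.target_position if target is None else target, dtype=float
    )
    is_look = spec.context == "look"
    r_target = scene.target_radius
    D = float(spec.target_distance)

    rt = _lognormal(params.rt_location, params.rt_scale, params.rt_sigma, rng) * mult["latency"]
    if is_look:
        rt += params.look_rt_penalty

    # primary movement toward a noisy aimpoint
    aim_angle = math.degrees(math.atan2(target[1] - start[1], target[0] - start[0]))
    aim_angle += params.bias_for(spec.target_angle)
    if params.angle_sd > 0:
        aim_angle += rng.normal(0.0, params.angle_sd * mult["noise"])
    extent = params.undershoot_frac * D
    if params.extent_cv > 0:
        extent += rng.normal(0.0, params.extent_cv * D * mult["noise"])
    extent = max(extent, 0.05 * D)
    T1 = (params.mt_intercept + params.mt_slope * D) * mult["mt"]

    traj = _Trajectory()
    traj.add(-1.0, rt, start, (0.0, 0.0))  # pre-onset hold (covers t = 0)
    u = np.array([math.cos(math.radians(aim_angle)), math.sin(math.radians(aim_angle))])
    traj.add(rt, rt + T1, start, extent * u)
    p = start + extent * u
    t_cur = rt + T1
    n_sub = 1

    while math.hypot(*(p - target)) > r_target and n_sub < params.max_submovements:
        lat = params.corr_latency * mult["latency"]
        if is_look:
            lat += params.look_corr_penalty
        err = target - p
        amp = params.corr_gain * math.hypot(*err)
        if params.extent_cv > 0:
            amp *= 1.0 + rng.normal(0.0, params.extent_cv * mult["noise"])
        amp = max(amp, 1e-4)
        ang = math.degrees(math.atan2(err[1], err[0]))
        if params.angle_sd > 0:
            ang += rng.normal(0.0, params.angle_sd * mult["noise"])
        Tc = (params.mt_intercept + params.mt_slope * amp) * mult["mt"]
        traj.add(t_cur, t_cur + lat, p, (0.0, 0.0))
        uc = np.array([math.cos(math.radians(ang)), math.sin(math.radians(ang))])
        traj.add(t_cur + lat, t_cur + lat + Tc, p, amp * uc)
        p = p + amp * uc
        t_cur += lat + Tc
        n_sub += 1

    inside = math.hypot(*(p - target)) <= r_target
    dwell = _lognormal(params.dwell_location, params.dwell_scale, params.dwell_sigma, rng)
    dwell *= mult["latency"]
    dt = params.frame_dt
    click_t = math.ceil((t_cur + dwell) / dt - 1e-9) * dt
    traj.add(t_cur, click_t + 3 * dt, p, (0.0, 0.0))
    success = inside and (time_limit is None or click_t <= time_limit)

    # frame-sampled trace
    n_frames = int(round(click_t / dt)) + 3
    t_ms = dt * np.arange(n_frames)
    path = traj.pos(t_ms)
    dx = np.zeros(n_frames)
    dy = np.zeros(n_frames)
    dx[1:] = np.diff(path[:, 0]) / scene.gain
    dy[1:] = np.diff(path[:, 1]) / scene.gain

    # event log from the sampled trace (game semantics: per-frame polling)
    events: list[tuple[float, str]] = [(0.0, "target_shown")]
    in_mask = np.hypot(path[:, 0] - target[0], path[:, 1] - target[1]) <= r_target
    for i in range(1, n_frames):
        if in_mask[i] and not in_mask[i - 1]:
            events.append((float(t_ms[i]), "target_enter"))
        elif in_mask[i - 1] and not in_mask[i]:
            events.append((float(t_ms[i]), "target_exit"))
    events = [ev for ev in events if ev[0] <= click_t]
    events.append((click_t, "click"))
    events.append((click_t, "success" if success else "fail"))

    gt = None
    if with_ground_truth and inside:
        crossings = _threshold_crossings(extent, T1)
        if crossings is not None:
            entry = _last_entry_time(traj, target, r_target, click_t)
            if entry is not None:
                gt = GroundTruth(
                    true_onset=rt + crossings[0],
                    true_primary_end=rt + crossings[1],
                    true_last_entry=entry,
                    true_click=click_t,
                )

    return TrialRecord(
        trial_id=trial_id,
        context=spec.context,
        target_distance=D,
        target_angle=spec.target_angle,
        start_pos=(float(start[0]), float(start[1])),
        target_pos=(float(target[0]), float(target[1])),
        t_ms=t_ms,
        dx=dx,
        dy=dy,
        x=path[:, 0],
        y=path[:, 1],
        events=events,
        success=bool(success),
        staircase_id=spec.staircase_id,
        time_limit=time_limit,
        round_index=round_index,
        cycle_index=spec.cycle_index,
        n_submovements=n_sub,
        ground_truth=gt,
    )


# ---------------------------------------------------------------------------
# full sessions

def simulate_experiment1(
    params: PerformerParams,
    rng: np.random.Generator,
    *,
    contexts: tuple[str, str] = ("point", "look"),
    scene: SceneConfig | None = None,
    with_ground_truth: bool = False,
    seed: int | None = None,
) -> Session:
    """One participant's Experiment-1 session: a 320-trial staircased block
    per context (640 trials), with per-trial staircase bookkeeping recorded
    on the trial rows (staircase id and the limit in effect)."""
    scene = scene or SceneConfig()
    trials: list[TrialRecord] = []
    for context in contexts:
        states = {
            sid: StaircaseState(limit=lim) for sid, lim in STAIRCASE_STARTS_MS.items()
        }
        for spec in exp1_block(context, rng):
            limit = states[spec.staircase_id].limit
            rec = simulate_trial(
                params,
                spec,
                limit,
                rng,
                scene=scene,
                trial_id=len(trials),
                with_ground_truth=with_ground_truth,
            )
            states[spec.staircase_id] = staircase_update(states[spec.staircase_id], rec.success)
            trials.append(rec)
    return Session(experiment="exp1", trials=trials, scene=scene.to_dict(), seed=seed)


def simulate_experiment2(
    params: PerformerParams,
    rng: np.random.Generator,
    *,
    n_rounds: int = 20,
    scene: SceneConfig | None = None,
    with_ground_truth: bool = False,
    seed: int | None = None,
) -> Session:
    """One participant's Experiment-2 session: ``n_rounds`` rounds of 48
    chained Look-context movements with dual-rate practice improvement.

    Each movement starts at the previous target (the round's first at the
    plane center).  The aim-trainer has no time limit, so every target is
    eventually acquired; in the rare event the correction-loop cap trips,
    the trial is recorded as a failure and the chain continues from the
    scheduled target.
    """
    scene = scene or SceneConfig()
    trials: list[TrialRecord] = []
    for round_index, round_spec in enumerate(exp2_session(rng, n_rounds)):
        mult = learning_multipliers(round_index, params)
        start = np.zeros(2)
        for pos, (dist, ang) in zip(round_spec.targets, round_spec.combo_labels):
            spec = TrialSpec(
                context="look",
                target_angle=ang,
                target_distance=dist,
                target_position=(float(pos[0]), float(pos[1])),
            )
            rec = simulate_trial(
                params,
                spec,
                None,
                rng,
                start=start,
                target=pos,
                scene=scene,
                trial_id=len(trials),
                round_index=round_index,
                multipliers=mult,
                with_ground_truth=with_ground_truth,
            )
            trials.append(rec)
            start = np.asarray(pos, dtype=float)
    return Session(experiment="exp2", trials=trials, scene=scene.to_dict(), seed=seed)
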
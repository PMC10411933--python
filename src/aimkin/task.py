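"""Trial schedules and adaptive staircase logic.

Experiment 1 is a staircased center-out shooting block: 320 trials per
context, arranged in 40 cycles of the 8 target angles (45 deg grid, 1 au
radius), with two interleaved one-up/one-down time-limit staircases starting
at 300 and 1,500 ms and moving in 30 ms steps.  Experiment 2 is an
aim-trainer session: 20 rounds of 48 chained targets covering all 24
(distance x angle) combinations twice per round, never leaving a 1 au
workspace radius.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "ANGLES_DEG",
    "EXP1_DISTANCE",
    "EXP2_DISTANCES",
    "STAIRCASE_STEP_MS",
    "STAIRCASE_STARTS_MS",
    "StaircaseState",
    "TrialSpec",
    "RoundSpec",
    "staircase_update",
    "interleave_schedule",
    "exp1_block",
    "asymptotic_time_limit",
    "exp2_round",
    "exp2_session",
    "run_staircase_block",
]

ANGLES_DEG: tuple[float, ...] = tuple(float(a) for a in range(0, 360, 45))
EXP1_DISTANCE: float = 1.0
EXP2_DISTANCES: tuple[float, ...] = (0.4, 0.6, 0.8)
STAIRCASE_STEP_MS: float = 30.0
STAIRCASE_STARTS_MS: dict[str, float] = {"low": 300.0, "high": 1500.0}
EXP1_TRIALS_PER_BLOCK: int = 320
EXP2_ROUNDS: int = 20


def _target_position(distance: float, angle_deg: float) -> tuple[float, float]:
    a = np.radians(angle_deg)
    return (distance * float(np.cos(a)), distance * float(np.sin(a)))


@dataclass(frozen=True)
class StaircaseState:
    """One one-up/one-down staircase over the trial time limit.

    ``history`` records ``(limit_in_effect, success)`` per completed trial;
    consecutive limits differ by exactly one step.  ``clamped`` flags that
    the floor (one step above zero) was ever hit.
    """

    limit: float
    step: float = STAIRCASE_STEP_MS
    history: tuple[tuple[float, bool], ...] = ()
    clamped: bool = False

    def __post_init__(self) -> None:
        if not self.limit > 0:
            raise ValueError("staircase limit must be positive")
        if not self.step > 0:
            raise ValueError("staircase step must be positive")

    @property
    def limits_used(self) -> np.ndarray:
        return np.array([lim for lim, _ in self.history])

    @property
    def successes(self) -> np.ndarray:
        return np.array([ok for _, ok in self.history], dtype=bool)


def staircase_update(state: StaircaseState, success: bool) -> StaircaseState:
    """Apply the one-up/one-down rule: success lowers the limit by one step,
    failure raises it.  A limit that would fall to <= 0 is clamped at one
    step and flagged (unreachable in sane simulations)."""
    new_limit = state.limit - state.step if success else state.limit + state.step
    clamped = state.clamped
    if new_limit <= 0:
        new_limit = state.step
        clamped = True
    return replace(
        state,
        limit=new_limit,
        history=state.history + ((state.limit, bool(success)),),
        clamped=clamped,
    )


def interleave_schedule(n_trials: int, rng: np.random.Generator) -> list[str]:
    """Assign staircases to trials in balanced shuffled pairs.

    Each consecutive pair of trials contains one "low" and one "high" trial
    in random order, so the tested staircase switches after most trials and
    never repeats more than twice in a row, with exactly n/2 trials each.
    """
    if n_trials % 2:
        raise ValueError(f"n_trials must be even, got {n_trials}")
    out: list[str] = []
    for _ in range(n_trials // 2):
        pair = ["low", "high"]
        if rng.random() < 0.5:
            pair.reverse()
        out.extend(pair)
    return out


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled shot attempt."""

    context: str
    target_angle: float
    target_distance: float
    target_position: tuple[float, float]
    staircase_id: str | None = None
    cycle_index: int = 0


def exp1_block(context: str, rng: np.random.Generator, n_cycles: int = 40) -> list[TrialSpec]:
    """A 320-trial Experiment-1 block: ``n_cycles`` cycles of the 8 angles,
    each cycle a fresh uniform permutation, with staircase ids interleaved."""
    if context not in ("point", "look"):
        raise ValueError(f"unknown context {context!r}")
    n_trials = n_cycles * len(ANGLES_DEG)
    ids = interleave_schedule(n_trials, rng)
    specs: list[TrialSpec] = []
    for cycle in range(n_cycles):
        for angle in rng.permutation(ANGLES_DEG):
            specs.append(
                TrialSpec(
                    context=context,
                    target_angle=float(angle),
                    target_distance=EXP1_DISTANCE,
                    target_position=_target_position(EXP1_DISTANCE, float(angle)),
                    staircase_id=ids[len(specs)],
                    cycle_index=cycle,
                )
            )
    return specs


def asymptotic_time_limit(
    limits: Sequence[float],
    staircase_ids: Sequence[str],
    window: int = 40,
    per_staircase: bool = True,
) -> float:
    """Asymptotic (skill) time limit of a staircased block.

    With ``per_staircase=True`` (default) the last ``window`` per-trial
    limits of *each* staircase are pooled (2 x window values) and their
    median returned; with ``per_staircase=False`` the last ``window`` trials
    of the block overall are pooled instead.
    """
    limits = np.asarray(limits, dtype=float)
    ids = np.asarray(staircase_ids)
    if limits.shape != ids.shape:
        raise ValueError("limits and staircase_ids must have equal length")
    if per_staircase:
        pools = []
        for sid in np.unique(ids):
            sel = limits[ids == sid]
            if sel.size < window:
                raise ValueError(
                    f"staircase {sid!r} has {sel.size} trials, needs >= {window}"
                )
            pools.append(sel[-window:])
        pooled = np.concatenate(pools)
    else:
        if limits.size < window:
            raise ValueError(f"block has {limits.size} trials, needs >= {window}")
        pooled = limits[-window:]
    return float(np.median(pooled))


@dataclass(frozen=True)
class RoundSpec:
    """One Experiment-2 round: 48 chained target positions with their
    (distance, angle) displacement labels."""

    targets: np.ndarray  # (48, 2)
    combo_labels: tuple[tuple[float, float], ...]  # (distance, angle) per target

    def validate(self, max_radius: float = 1.0, atol: float = 1e-9) -> None:
        n_combos = len(EXP2_DISTANCES) * len(ANGLES_DEG)
        if self.targets.shape != (2 * n_combos, 2):
            raise ValueError(f"round must contain {2 * n_combos} targets")
        from collections import Counter

        counts = Counter(self.combo_labels)
        if len(counts) != n_combos or any(c != 2 for c in counts.values()):
            raise ValueError("each (distance, angle) combination must occur exactly twice")
        radii = np.hypot(self.targets[:, 0], self.targets[:, 1])
        if np.any(radii > max_radius + atol):
            raise ValueError(f"target beyond {max_radius} au from plane center")
        prev = np.zeros(2)
        for pos, (dist, ang) in zip(self.targets, self.combo_labels):
            step = pos - prev
            expect = np.array(_target_position(dist, ang))
            if not np.allclose(step, expect, atol=atol):
                raise ValueError("target displacement does not match its combo label")
            prev = pos


def _sample_cycle(
    rng: np.random.Generator,
    vecs: np.ndarray,
    max_radius: float,
    max_attempts: int,
) -> np.ndarray:
    """Rejection-sample one cycle order whose chained positions stay within
    ``max_radius`` of the plane center.  Because every cycle's displacement
    vectors sum to zero (each angle carries all three distances), a cycle is
    a closed loop from the center, so cycles can be sampled independently."""
    for _ in range(max_attempts):
        order = rng.permutation(len(vecs))
        pos = np.cumsum(vecs[order], axis=0)
        if np.all(np.hypot(pos[:, 0], pos[:, 1]) <= max_radius + 1e-12):
            return order
    raise RuntimeError(f"no admissible cycle found in {max_attempts} attempts")


def exp2_round(
    rng: np.random.Generator,
    distances: Sequence[float] = EXP2_DISTANCES,
    angles: Sequence[float] = ANGLES_DEG,
    max_radius: float = 1.0,
    max_attempts: int = 1_000_000,
) -> RoundSpec:
    """Generate one 48-target round by rejection sampling.

    Two cycles; within each cycle the 24 (distance, angle) combinations are
    shuffled and chained as displacements — the round's first target is
    itself a combo displacement from the plane center.  Any chained position
    farther than ``max_radius`` from the center rejects the cycle and a new
    shuffle is drawn.
    """
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    combos = [(float(d), float(a)) for d in distances for a in angles]
    vecs = np.array([_target_position(d, a) for d, a in combos])
    targets = []
    labels: list[tuple[float, float]] = []
    for _cycle in range(2):
        order = _sample_cycle(rng, vecs, max_radius, max_attempts)
        targets.append(np.cumsum(vecs[order], axis=0))
        labels.extend(combos[i] for i in order)
    return RoundSpec(targets=np.vstack(targets), combo_labels=tuple(labels))


def exp2_session(rng: np.random.Generator, n_rounds: int = EXP2_ROUNDS, **kwargs) -> list[RoundSpec]:
    """``n_rounds`` independent rounds (defaults: 20 rounds, 960 targets)."""
    return [exp2_round(rng, **kwargs) for _ in range(n_rounds)]


def run_staircase_block(
    success_prob,
    rng: np.random.Generator,
    n_trials: int = EXP1_TRIALS_PER_BLOCK,
    starts: dict[str, float] | None = None,
    step: float = STAIRCASE_STEP_MS,
) -> dict[str, StaircaseState]:
    """Drive the two interleaved staircases with a probabilistic performer.

    ``success_prob(limit_ms)`` gives the probability of success at a given
    time limit (a deterministic threshold performer returns 0/1).  Returns
    the final per-staircase states, whose histories carry the per-trial
    limits and outcomes.
    """
    starts = dict(STAIRCASE_STARTS_MS if starts is None else starts)
    states = {sid: StaircaseState(limit=lim, step=step) for sid, lim in starts.items()}
    for sid in interleave_schedule(n_trials, rng):
        ok = rng.random() < success_prob(states[sid].limit)
        states[sid] = staircase_update(states[sid], ok)
    return states
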
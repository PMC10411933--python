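"""In-memory containers for trial and session data.

A :class:`TrialRecord` holds everything the game would log for one shot
attempt: the schedule entry, the raw per-frame input trace (timestamps,
device deltas, cursor positions), the event timeline, and the outcome.
Simulated trials may additionally carry :class:`GroundTruth` phase labels
for validating the segmentation stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["GroundTruth", "TrialRecord", "Session", "EVENT_NAMES"]

EVENT_NAMES = ("target_shown", "target_enter", "target_exit", "click", "success", "fail")


@dataclass(frozen=True)
class GroundTruth:
    """Generative phase-boundary labels (ms from target onset).

    Boundaries are stated in the same convention the segmenter estimates:
    onset and primary end are the analytic 0.5 au/s radial-speed crossings
    of the noiseless generated profile, last entry is the exact time the
    cursor crosses the target boundary for the last time before the click.
    Onset <= primary end <= click; the last entry may precede the primary
    end when the primary movement itself carries the cursor into the target
    (the analysis clamps the correction phase to zero in that case).
    """

    true_onset: float
    true_primary_end: float
    true_last_entry: float
    true_click: float

    def __post_init__(self) -> None:
        ordered = (
            self.true_onset <= self.true_primary_end <= self.true_click
            and self.true_onset <= self.true_last_entry <= self.true_click
        )
        if not ordered:
            raise ValueError(
                "ground-truth boundaries out of order: "
                f"{(self.true_onset, self.true_primary_end, self.true_last_entry, self.true_click)}"
            )


@dataclass
class TrialRecord:
    """One shot attempt: schedule metadata, raw trace, events, outcome.

    Trace arrays are per frame sample: ``t_ms`` strictly increasing,
    ``dx/dy`` raw device deltas since the previous sample, ``x/y`` the
    analysis-space cursor position (au).  ``events`` is a time-sorted list
    of ``(t_ms, name)`` with names from :data:`EVENT_NAMES`.
    """

    trial_id: int
    context: str
    target_distance: float
    target_angle: float
    start_pos: tuple[float, float]
    target_pos: tuple[float, float]
    t_ms: np.ndarray
    dx: np.ndarray
    dy: np.ndarray
    x: np.ndarray
    y: np.ndarray
    events: list[tuple[float, str]]
    success: bool
    staircase_id: str | None = None
    time_limit: float | None = None
    round_index: int | None = None
    cycle_index: int | None = None
    n_submovements: int = 0
    ground_truth: GroundTruth | None = None

    @property
    def path(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def event_time(self, name: str) -> float | None:
        """Time of the last event with this name, or None."""
        times = [t for t, n in self.events if n == name]
        return times[-1] if times else None

    def frame_rate(self) -> float:
        """Mean frames per second over the trial's trace."""
        if self.t_ms.size < 2:
            return float("nan")
        return 1000.0 * (self.t_ms.size - 1) / float(self.t_ms[-1] - self.t_ms[0])


@dataclass
class Session:
    """A full experimental session: header metadata plus trial records."""

    experiment: str  # "exp1" | "exp2"
    trials: list[TrialRecord] = field(default_factory=list)
    scene: dict = field(default_factory=dict)
    device: str = "mouse"
    seed: int | None = None
    format_version: int = 1

    def __len__(self) -> int:
        return len(self.trials)

    def by_context(self, context: str) -> list[TrialRecord]:
        return [tr for tr in self.trials if tr.context == context]
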
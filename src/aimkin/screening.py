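"""Participant-level data-quality screening.

Three exclusion rules: (1) frame rate — sessions rendered below 30 fps, or
whose frame rate differs by more than 10 fps between contexts (Experiment 1)
or drops by more than 10 fps between the first and last round (Experiment
2); (2) stabilization — Experiment-1 blocks whose success rate over the last
40 trials of both staircases sits more than 10 percentage points from the
intended 50%; (3) robust outliers — values more than 3 scaled median
absolute deviations (consistency constant 1.4826) from the group median.

All boundary comparisons are strict (exactly 10 fps difference or exactly
60% success passes).  Screening never mutates data; it returns annotations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .records import Session

__all__ = [
    "MAD_CONSISTENCY",
    "ScreeningReport",
    "mad_outliers",
    "frame_rate_check_exp1",
    "frame_rate_check_exp2",
    "stabilization_check",
    "screen_session",
]

#: Scale factor making the MAD a consistent estimator of the SD of a normal.
MAD_CONSISTENCY = 1.4826
MIN_FPS = 30.0
MAX_FPS_DIFF = 10.0
SUCCESS_TOLERANCE = 0.10


@dataclass
class ScreeningReport:
    """Outcome of the applicable checks for one participant/session."""

    participant: str | int | None = None
    frame_rate_pass: bool | None = None
    stabilization_pass: bool | None = None
    outlier_pass: bool | None = None
    reasons: list[str] = field(default_factory=list)
    values: dict = field(default_factory=dict)

    @property
    def overall_pass(self) -> bool:
        checks = [self.frame_rate_pass, self.stabilization_pass, self.outlier_pass]
        return all(c for c in checks if c is not None)


def mad_outliers(values, k: float = 3.0, c: float = MAD_CONSISTENCY) -> np.ndarray:
    """Boolean mask of values more than ``k`` scaled MADs from the median.

    The mask is invariant to affine transforms of the input.  Degenerate
    case (MAD = 0): any value differing from the median is flagged, matching
    the robust-z limit.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 values")
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    if mad == 0:
        return x != med
    return np.abs(x - med) > k * c * mad


def frame_rate_check_exp1(
    fps_by_context: dict[str, float],
    min_fps: float = MIN_FPS,
    max_diff: float = MAX_FPS_DIFF,
) -> tuple[bool, list[str]]:
    """Fail if the mean frame rate is below ``min_fps`` in either context or
    the contexts differ by more than ``max_diff`` fps (both strict)."""
    reasons = []
    for ctx, fps in fps_by_context.items():
        if fps < min_fps:
            reasons.append(f"{ctx} frame rate {fps:.1f} fps < {min_fps:g} fps")
    vals = list(fps_by_context.values())
    if len(vals) == 2 and abs(vals[0] - vals[1]) > max_diff:
        reasons.append(f"context frame-rate difference {abs(vals[0] - vals[1]):.1f} fps > {max_diff:g} fps")
    return not reasons, reasons


def frame_rate_check_exp2(
    mean_fps: float,
    first_round_fps: float,
    last_round_fps: float,
    min_fps: float = MIN_FPS,
    max_drop: float = MAX_FPS_DIFF,
) -> tuple[bool, list[str]]:
    """Fail if the session-average frame rate is below ``min_fps`` or the
    frame rate dropped by more than ``max_drop`` fps from the first to the
    last round."""
    reasons = []
    if mean_fps < min_fps:
        reasons.append(f"average frame rate {mean_fps:.1f} fps < {min_fps:g} fps")
    drop = first_round_fps - last_round_fps
    if drop > max_drop:
        reasons.append(f"frame rate dropped {drop:.1f} fps between first and last round > {max_drop:g} fps")
    return not reasons, reasons


def stabilization_check(
    success_rate_by_context: dict[str, float],
    target: float = 0.5,
    tolerance: float = SUCCESS_TOLERANCE,
) -> tuple[bool, list[str]]:
    """Fail if the last-window success rate is more than ``tolerance`` from
    the staircase's intended ``target`` rate in any context (strict)."""
    reasons = []
    for ctx, rate in success_rate_by_context.items():
        if abs(rate - target) > tolerance:
            reasons.append(
                f"{ctx} last-window success rate {rate:.3f} more than "
                f"{tolerance:.0%} from {target:.0%}"
            )
    return not reasons, reasons


def screen_session(session: Session, trials_df: pd.DataFrame, window: int = 40) -> ScreeningReport:
    """Run the applicable checks on one session.

    ``trials_df`` is the tidy table from :func:`aimkin.metrics.trials_table`
    (it carries per-trial fps and success).  The MAD outlier rule is a
    group-level check and is left None here.
    """
    report = ScreeningReport(participant=session.seed)
    if session.experiment == "exp1":
        fps_ctx = {
            ctx: float(grp["fps"].mean()) for ctx, grp in trials_df.groupby("context", sort=False)
        }
        ok, reasons = frame_rate_check_exp1(fps_ctx)
        report.frame_rate_pass = ok
        report.reasons += reasons
        report.values["fps_by_context"] = fps_ctx

        from .metrics import exp1_selection_mask

        sel = trials_df[exp1_selection_mask(trials_df, window)]
        rates = {
            ctx: float(grp["success"].mean()) for ctx, grp in sel.groupby("context", sort=False)
        }
        ok, reasons = stabilization_check(rates)
        report.stabilization_pass = ok
        report.reasons += reasons
        report.values["last_window_success"] = rates
    else:
        by_round = trials_df.groupby("round_index")["fps"].mean()
        ok, reasons = frame_rate_check_exp2(
            float(trials_df["fps"].mean()),
            float(by_round.iloc[0]),
            float(by_round.iloc[-1]),
        )
        report.frame_rate_pass = ok
        report.reasons += reasons
        report.values["mean_fps"] = float(trials_df["fps"].mean())
        report.values["first_round_fps"] = float(by_round.iloc[0])
        report.values["last_round_fps"] = float(by_round.iloc[-1])
    return report
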
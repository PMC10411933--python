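"""Trajectory segmentation into the four movement phases.

A successful shot decomposes as: reaction time (target shown to movement
onset), primary movement time (onset to the end of the primary, largely
feedforward movement), correction time (primary end to the last entry into
the target), and click dwell (last entry to the successful click).  Onset is
the first sample whose radial speed exceeds 0.5 au/s; the primary end is
located from discontinuities in the (tangential) speed profile: the first
post-peak local minimum below half the peak, or the first drop below the
onset threshold, whichever comes first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import TrialRecord

__all__ = [
    "SpeedSeries",
    "Segmentation",
    "DataInconsistencyError",
    "ONSET_THRESHOLD",
    "compute_speed",
    "detect_onset",
    "detect_primary_end",
    "target_entries",
    "segment_trial",
]

#: Default movement-onset radial-speed threshold (au/s).
ONSET_THRESHOLD = 0.5
#: Default fraction of peak speed below which a local minimum ends the
#: primary movement.
PRIMARY_END_PEAK_FRAC = 0.5
#: Default moving-average window (samples, odd) applied to speed profiles.
#: 1 = no smoothing: simulated traces are already band-limited, and an
#: unsmoothed profile keeps threshold crossings free of curvature-induced
#: lag; raise to 3-5 for jittery real recordings.
SPEED_SMOOTHING_WINDOW = 1


class DataInconsistencyError(ValueError):
    """The event log contradicts the sampled trajectory."""


@dataclass
class SpeedSeries:
    """Speeds at interior trace samples (the differentiation margin drops
    the first and last sample).  ``radial_speed`` is d|cursor - start|/dt
    (signed: negative when moving back toward the start); ``tangential_speed``
    is the path speed, non-negative.  Units au/s, times ms."""

    t: np.ndarray
    radial_speed: np.ndarray
    tangential_speed: np.ndarray
    smoothed: bool = False


def _smooth(values: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return values
    if window % 2 == 0:
        raise ValueError("smoothing window must be odd")
    kernel = np.ones(window) / window
    # centered moving average with edge shrinkage
    padded = np.pad(values, window // 2, mode="edge")
    return np.convolve(padded, kernel, mode="valid")


def _central_derivative(values: np.ndarray, t_ms: np.ndarray) -> np.ndarray:
    """Derivative (per second) at the interior samples t[1:-1].

    Second-order central differences; on uniformly sampled traces the deep
    interior (two samples from each edge) is upgraded to the fourth-order
    five-point stencil, which keeps per-sample speed estimates accurate
    enough that threshold crossings are located to within one sample.
    """
    dt_s = (t_ms[2:] - t_ms[:-2]) / 1000.0
    deriv = (values[2:] - values[:-2]) / dt_s
    steps = np.diff(t_ms)
    if len(values) >= 5 and np.allclose(steps, steps[0], rtol=1e-9, atol=1e-9):
        h = steps[0] / 1000.0
        deriv[1:-1] = (
            -values[4:] + 8 * values[3:-1] - 8 * values[1:-3] + values[:-4]
        ) / (12.0 * h)
    return deriv


def compute_speed(
    path: np.ndarray,
    t_ms: np.ndarray,
    start=None,
    window: int = SPEED_SMOOTHING_WINDOW,
) -> SpeedSeries:
    """Central-difference radial and tangential speed of a cursor path.

    ``start`` defaults to the first path sample.  A centered moving average
    of odd width ``window`` (1, the default, disables it) is applied to the
    speeds only, never to the positions.
    """
    path = np.asarray(path, dtype=float)
    t_ms = np.asarray(t_ms, dtype=float)
    if path.shape[0] != t_ms.shape[0]:
        raise ValueError("path and timestamps must have equal length")
    if path.shape[0] < 3:
        raise ValueError("need at least 3 samples to differentiate")
    if np.any(np.diff(t_ms) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    start = path[0] if start is None else np.asarray(start, dtype=float)

    radial = np.hypot(path[:, 0] - start[0], path[:, 1] - start[1])
    radial_speed = _central_derivative(radial, t_ms)
    vx = _central_derivative(path[:, 0], t_ms)
    vy = _central_derivative(path[:, 1], t_ms)
    tangential_speed = np.hypot(vx, vy)

    smoothed = window > 1
    return SpeedSeries(
        t=t_ms[1:-1],
        radial_speed=_smooth(radial_speed, window),
        tangential_speed=_smooth(tangential_speed, window),
        smoothed=smoothed,
    )


def detect_onset(
    speed: SpeedSeries,
    target_shown_t: float,
    threshold: float = ONSET_THRESHOLD,
) -> float | None:
    """Movement onset: first sample after ``target_shown_t`` whose radial
    speed exceeds ``threshold``; None if never crossed (no-movement trial).
    """
    mask = (speed.t > target_shown_t) & (speed.radial_speed > threshold)
    idx = np.nonzero(mask)[0]
    return float(speed.t[idx[0]]) if idx.size else None


def detect_primary_end(
    speed: SpeedSeries,
    onset_t: float,
    click_t: float | None = None,
    peak_frac: float = PRIMARY_END_PEAK_FRAC,
    threshold: float = ONSET_THRESHOLD,
) -> float:
    """End of the primary movement.

    After the peak tangential speed (at or after onset), the primary
    movement ends at the earliest sample that is either (a) a local minimum
    of tangential speed below ``peak_frac`` of the peak, or (b) below the
    onset ``threshold``.  If neither occurs before the end of the series,
    ``click_t`` (or the last sample time) is returned.
    """
    sel = np.nonzero(speed.t >= onset_t)[0]
    if not sel.size:
        raise ValueError("onset_t beyond the speed series")
    v = speed.tangential_speed[sel[0]:]
    t = speed.t[sel[0]:]
    peak_i = int(np.argmax(v))
    peak = v[peak_i]
    for i in range(peak_i + 1, len(v)):
        if v[i] < threshold:
            return float(t[i])
        is_local_min = v[i] < v[i - 1] and (i + 1 == len(v) or v[i] <= v[i + 1])
        if is_local_min and v[i] < peak_frac * peak:
            return float(t[i])
    return float(click_t if click_t is not None else t[-1])


def target_entries(
    path: np.ndarray,
    t_ms: np.ndarray,
    target_center,
    target_diameter: float,
) -> list[tuple[float, float]]:
    """Intervals during which the cursor center is on or inside the target
    circle (boundary inclusive).  Each interval is (entry time, time of the
    last inside sample); an interval open at the trace end closes at the
    final sample."""
    path = np.asarray(path, dtype=float)
    t_ms = np.asarray(t_ms, dtype=float)
    c = np.asarray(target_center, dtype=float)
    # 1e-12 guard keeps the inclusive boundary robust to float rounding
    inside = np.hypot(path[:, 0] - c[0], path[:, 1] - c[1]) <= target_diameter / 2.0 + 1e-12
    intervals: list[tuple[float, float]] = []
    i = 0
    n = len(inside)
    while i < n:
        if inside[i]:
            j = i
            while j + 1 < n and inside[j + 1]:
                j += 1
            intervals.append((float(t_ms[i]), float(t_ms[j])))
            i = j + 1
        else:
            i += 1
    return intervals


@dataclass
class Segmentation:
    """Phase boundaries (ms, trial clock) and durations of one trial.

    ``acquire`` is stored as the sum of the four phase durations so the
    decomposition identity holds exactly in floating point.  Boundaries that
    cannot be determined (unsuccessful or no-movement trials) are None, and
    the dependent durations are NaN.
    """

    onset_t: float | None
    primary_end_t: float | None
    last_entry_t: float | None
    click_t: float | None
    reaction: float
    primary_mt: float
    correction: float
    dwell: float
    acquire: float
    no_movement: bool = False

    @property
    def complete(self) -> bool:
        return not self.no_movement and None not in (
            self.onset_t,
            self.primary_end_t,
            self.last_entry_t,
            self.click_t,
        )


def _partial(onset_t=None, primary_end_t=None, click_t=None, no_movement=False) -> Segmentation:
    nan = float("nan")
    return Segmentation(
        onset_t=onset_t,
        primary_end_t=primary_end_t,
        last_entry_t=None,
        click_t=click_t,
        reaction=nan,
        primary_mt=nan,
        correction=nan,
        dwell=nan,
        acquire=nan,
        no_movement=no_movement,
    )


def segment_trial(
    record: TrialRecord,
    threshold: float = ONSET_THRESHOLD,
    peak_frac: float = PRIMARY_END_PEAK_FRAC,
    window: int = SPEED_SMOOTHING_WINDOW,
    target_diameter: float = 0.2,
) -> Segmentation:
    """Segment one trial into the four phases.

    Successful trials yield all four boundaries and the exact-sum identity
    reaction + primary_mt + correction + dwell = acquire.  If the cursor is
    already inside the target when the primary movement ends, the correction
    phase is clamped to zero and dwell runs from the primary end.
    Unsuccessful trials yield partial segmentations.

    Segmentation depends only on the analysis-space path, so it is invariant
    to the trial's context flag.
    """
    shown_t = record.event_time("target_shown")
    if shown_t is None:
        raise DataInconsistencyError("trial has no target_shown event")
    speed = compute_speed(record.path, record.t_ms, start=record.start_pos, window=window)

    onset_t = detect_onset(speed, shown_t, threshold)
    if onset_t is None:
        return _partial(no_movement=True)

    click_t = record.event_time("click")
    primary_end_t = detect_primary_end(speed, onset_t, click_t, peak_frac, threshold)
    if click_t is not None:
        # the trace extends a little past the click; the primary movement
        # cannot end after the trial did
        primary_end_t = min(primary_end_t, click_t)
    if click_t is None:
        return _partial(onset_t=onset_t, primary_end_t=primary_end_t)

    entries = target_entries(record.path, record.t_ms, record.target_pos, target_diameter)
    containing = [(e, x) for e, x in entries if e <= click_t + 1e-9 and click_t <= x + 1e-9]
    if not containing:
        if record.success:
            raise DataInconsistencyError(
                f"trial {record.trial_id}: successful click at {click_t} ms lies "
                "outside every target-entry interval"
            )
        return _partial(onset_t=onset_t, primary_end_t=primary_end_t, click_t=click_t)
    last_entry_t = containing[-1][0]

    reaction = onset_t - shown_t
    primary_mt = primary_end_t - onset_t
    correction = max(0.0, last_entry_t - primary_end_t)
    dwell = click_t - max(last_entry_t, primary_end_t)
    return Segmentation(
        onset_t=onset_t,
        primary_end_t=primary_end_t,
        last_entry_t=last_entry_t,
        click_t=click_t,
        reaction=reaction,
        primary_mt=primary_mt,
        correction=correction,
        dwell=dwell,
        acquire=reaction + primary_mt + correction + dwell,
    )
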
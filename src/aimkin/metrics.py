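"""Per-trial spatial measures and per-participant summaries.

Covers the spatial metric suite of the aiming task: radial extent and hand
angle at the end of the primary movement, peak radial speed, target-aligned
endpoints with confidence error ellipses, a path linearity index, the
effective (post hoc) Fitts index of difficulty with its movement-time
regression, and per-angle directional bias.

Angle sign convention: counterclockwise positive, so a positive hand angle
means the movement deviated counterclockwise from the straight start-target
direction.  Target alignment rotates every movement as if its target were
directly up (+y), making the on-axis (extent) coordinate y and the off-axis
(direction) coordinate x.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.stats import chi2

from .kinematics import Segmentation, segment_trial
from .records import Session, TrialRecord

__all__ = [
    "TrialMetrics",
    "EllipseFit",
    "DegenerateCovarianceError",
    "FITTS_WE_FACTOR",
    "trial_metrics",
    "trials_table",
    "linearity_index",
    "error_ellipse",
    "directional_bias",
    "effective_id",
    "fitts_fit",
    "exp1_selection_mask",
    "participant_summary_exp1",
    "round_summary",
    "cell_summary",
]

#: Effective target width is 4.133 x the SD of the on-axis endpoint
#: coordinate (the width of the 96% interval of a normal endpoint spread).
FITTS_WE_FACTOR = 4.133


class DegenerateCovarianceError(ValueError):
    """Endpoint covariance is rank-deficient; ellipse undefined."""


def _wrap_deg(angle: float) -> float:
    return (angle + 180.0) % 360.0 - 180.0


@dataclass(frozen=True)
class TrialMetrics:
    """Spatial and temporal measures of one trial."""

    acquire: float
    reaction: float
    primary_mt: float
    correction: float
    dwell: float
    peak_speed: float
    extent_at_pe: float
    angle_at_pe: float
    endpoint_aligned: tuple[float, float]
    success: bool
    distance: float
    angle: float


def trial_metrics(record: TrialRecord, seg: Segmentation) -> TrialMetrics:
    """Spatial measures at the end of the primary movement plus the phase
    durations.

    extent_at_pe is the cursor's radial distance from the start at the
    primary end; angle_at_pe the signed (ccw-positive) deviation from the
    start->target direction; peak_speed the maximum radial speed between
    onset and click; endpoint_aligned the primary-end position rotated as
    if the target were directly up.
    """
    from .kinematics import compute_speed

    nan = float("nan")
    start = np.asarray(record.start_pos)
    target = np.asarray(record.target_pos)
    target_dir = math.degrees(math.atan2(*(target - start)[::-1]))

    peak_speed = nan
    extent = nan
    angle_err = nan
    aligned = (nan, nan)
    if seg.onset_t is not None and seg.primary_end_t is not None:
        idx = int(np.searchsorted(record.t_ms, seg.primary_end_t))
        idx = min(idx, len(record.t_ms) - 1)
        p = np.array([record.x[idx], record.y[idx]]) - start
        extent = float(np.hypot(*p))
        angle_err = _wrap_deg(math.degrees(math.atan2(p[1], p[0])) - target_dir)
        # rotate so the target direction maps to +y
        rot = math.radians(90.0 - target_dir)
        aligned = (
            float(p[0] * math.cos(rot) - p[1] * math.sin(rot)),
            float(p[0] * math.sin(rot) + p[1] * math.cos(rot)),
        )
        speed = compute_speed(record.path, record.t_ms, start=record.start_pos)
        stop_t = seg.click_t if seg.click_t is not None else record.t_ms[-1]
        win = (speed.t >= seg.onset_t) & (speed.t <= stop_t)
        if win.any():
            peak_speed = float(np.max(speed.radial_speed[win]))

    return TrialMetrics(
        acquire=seg.acquire,
        reaction=seg.reaction,
        primary_mt=seg.primary_mt,
        correction=seg.correction,
        dwell=seg.dwell,
        peak_speed=peak_speed,
        extent_at_pe=extent,
        angle_at_pe=angle_err,
        endpoint_aligned=aligned,
        success=record.success,
        distance=record.target_distance,
        angle=record.target_angle,
    )


def trials_table(session: Session, **segment_kwargs) -> pd.DataFrame:
    """Tidy per-trial table: segmentation and metrics for every trial."""
    rows = []
    for rec in session.trials:
        seg = segment_trial(rec, **segment_kwargs)
        m = trial_metrics(rec, seg)
        rows.append(
            {
                "trial_id": rec.trial_id,
                "context": rec.context,
                "staircase_id": rec.staircase_id,
                "time_limit": rec.time_limit,
                "round_index": rec.round_index,
                "distance": m.distance,
                "angle": m.angle,
                "success": m.success,
                "acquire": m.acquire,
                "reaction": m.reaction,
                "primary_mt": m.primary_mt,
                "correction": m.correction,
                "dwell": m.dwell,
                "peak_speed": m.peak_speed,
                "extent_at_pe": m.extent_at_pe,
                "angle_at_pe": m.angle_at_pe,
                "aligned_x": m.endpoint_aligned[0],
                "aligned_y": m.endpoint_aligned[1],
                "fps": rec.frame_rate(),
            }
        )
    return pd.DataFrame(rows)


def linearity_index(path: np.ndarray, start, target) -> float:
    """Maximum perpendicular deviation of the path from the straight
    start->target segment, normalized by the straight-line distance
    (0 for a perfectly straight movement; 0.5 for a semicircular arc)."""
    path = np.asarray(path, dtype=float)
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    if path.shape[0] < 2:
        raise ValueError("path needs at least 2 samples")
    chord = target - start
    dist = float(np.hypot(*chord))
    if dist == 0:
        raise ValueError("start and target coincide; linearity undefined")
    u = chord / dist
    rel = path - start
    perp = np.abs(rel[:, 0] * u[1] - rel[:, 1] * u[0])
    return float(np.max(perp) / dist)


@dataclass(frozen=True)
class EllipseFit:
    """Confidence error ellipse of a 2D endpoint cloud."""

    semi_axes: tuple[float, float]  # (major, minor), au
    orientation: float  # deg of the major axis, ccw from +x
    aspect_ratio: float
    coverage: float


def error_ellipse(endpoints: np.ndarray, coverage: float = 0.95) -> EllipseFit:
    """Fit a chi-square confidence ellipse to aligned endpoints.

    Semi-axis k = sqrt(q * lambda_k) with q the chi2(2 df) quantile at
    ``coverage`` and lambda the sample-covariance eigenvalues; the aspect
    ratio sqrt(lambda_major / lambda_minor) is quantile-free.
    """
    endpoints = np.asarray(endpoints, dtype=float)
    if endpoints.shape[0] < 3:
        raise ValueError("need at least 3 endpoints")
    cov = np.cov(endpoints, rowvar=False)
    evals, evecs = np.linalg.eigh(cov)
    if evals[0] <= 0 or not np.all(np.isfinite(evals)):
        raise DegenerateCovarianceError(
            f"endpoint covariance is degenerate (rank {np.linalg.matrix_rank(cov)})"
        )
    q = float(chi2.ppf(coverage, df=2))
    major, minor = float(evals[1]), float(evals[0])
    v = evecs[:, 1]
    return EllipseFit(
        semi_axes=(math.sqrt(q * major), math.sqrt(q * minor)),
        orientation=math.degrees(math.atan2(v[1], v[0])),
        aspect_ratio=math.sqrt(major / minor),
        coverage=coverage,
    )


def directional_bias(
    df: pd.DataFrame,
    angle_col: str = "angle",
    error_col: str = "angle_at_pe",
    participant_col: str | None = "participant",
) -> pd.Series:
    """Per-angle mean signed directional error.

    Takes the per-participant median error at each target angle, then the
    group mean; with no participant column the per-angle median is returned
    directly (a single-performer summary).
    """
    df = df.dropna(subset=[error_col])
    if participant_col and participant_col in df.columns:
        med = df.groupby([participant_col, angle_col])[error_col].median()
        return med.groupby(level=angle_col).mean()
    return df.groupby(angle_col)[error_col].median()


def effective_id(distance_mean: float, endpoints_aligned: np.ndarray) -> float:
    """Effective Fitts index of difficulty (bits) of one distance cell.

    W_e = 4.133 x SD of the signed on-axis (aligned y) endpoint coordinate;
    ID_e = log2(D_e / W_e + 1) with D_e the cell's mean movement extent.
    Returns NaN when the endpoint spread is zero (undefined).
    """
    endpoints_aligned = np.atleast_2d(np.asarray(endpoints_aligned, dtype=float))
    if endpoints_aligned.shape[0] < 2:
        raise ValueError("need at least 2 endpoints per cell")
    sd = float(np.std(endpoints_aligned[:, 1], ddof=1))
    if sd == 0:
        return float("nan")
    w_e = FITTS_WE_FACTOR * sd
    return math.log2(distance_mean / w_e + 1.0)


def fitts_fit(ids: np.ndarray, movement_times: np.ndarray) -> tuple[float, float]:
    """Ordinary least squares of movement time (ms) on effective ID (bits);
    returns (intercept ms, slope ms/bit)."""
    ids = np.asarray(ids, dtype=float)
    movement_times = np.asarray(movement_times, dtype=float)
    if np.unique(ids).size < 2:
        raise ValueError("need at least 2 distinct ID values")
    model = sm.OLS(movement_times, sm.add_constant(ids)).fit()
    return float(model.params[0]), float(model.params[1])


# ---------------------------------------------------------------------------
# participant summaries

def exp1_selection_mask(df: pd.DataFrame, window: int = 40) -> pd.Series:
    """Trials in the last ``window`` of each staircase within each context
    (the Experiment-1 analysis window; success is filtered separately)."""
    mask = pd.Series(False, index=df.index)
    for (_, _), grp in df.groupby(["context", "staircase_id"]):
        mask.loc[grp.index[-window:]] = True
    return mask


_TEMPORAL = ["acquire", "reaction", "primary_mt", "correction", "dwell"]


def participant_summary_exp1(df: pd.DataFrame, window: int = 40) -> pd.DataFrame:
    """Per-context summary over successful trials in the selection window.

    Reports the asymptotic time limit (median per-trial limit over the last
    ``window`` trials of each staircase, pooled), medians of the temporal
    measures, mean and SD of primary-movement extent, mean peak speed, and
    SD of the hand angle, plus the trial counts used.
    """
    from .task import asymptotic_time_limit

    sel = df[exp1_selection_mask(df, window)]
    rows = []
    for context, grp in sel.groupby("context", sort=False):
        ok = grp[grp["success"]]
        row = {
            "context": context,
            "n_selected": len(grp),
            "n_successful": len(ok),
            "asymptotic_limit": asymptotic_time_limit(
                grp["time_limit"].to_numpy(), grp["staircase_id"].to_numpy(), window=window
            ),
            "success_rate": float(grp["success"].mean()),
        }
        for col in _TEMPORAL:
            row[f"median_{col}"] = float(ok[col].median()) if len(ok) else float("nan")
        row["mean_extent"] = float(ok["extent_at_pe"].mean()) if len(ok) else float("nan")
        row["sd_extent"] = float(ok["extent_at_pe"].std(ddof=1)) if len(ok) > 1 else float("nan")
        row["mean_peak_speed"] = float(ok["peak_speed"].mean()) if len(ok) else float("nan")
        row["sd_angle"] = float(ok["angle_at_pe"].std(ddof=1)) if len(ok) > 1 else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


def round_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Experiment-2 learning curves: per-round medians of the temporal
    measures and summaries of the spatial ones."""
    rows = []
    for rnd, grp in df.groupby("round_index", sort=True):
        ok = grp[grp["success"]]
        row = {"round_index": rnd, "n_trials": len(grp), "n_successful": len(ok)}
        for col in _TEMPORAL:
            row[f"median_{col}"] = float(ok[col].median())
        # corrections are absent on movements that enter the target during
        # the primary reach, so their median is often 0; the mean keeps the
        # corrective phase visible in learning curves
        row["mean_correction"] = float(ok["correction"].mean())
        row["mean_extent"] = float(ok["extent_at_pe"].mean())
        row["sd_extent"] = float(ok["extent_at_pe"].std(ddof=1))
        row["mean_peak_speed"] = float(ok["peak_speed"].mean())
        row["sd_angle"] = float(ok["angle_at_pe"].std(ddof=1))
        rows.append(row)
    return pd.DataFrame(rows)


def cell_summary(df: pd.DataFrame, coverage: float = 0.95) -> pd.DataFrame:
    """Experiment-2 per-(distance, angle) and per-distance summaries used
    for the classic-reaching analyses.

    Per distance: median movement time (onset to click: primary + correction
    + dwell), median peak speed and its SD, the effective ID of the cell,
    and the endpoint-ellipse aspect ratio.
    """
    ok = df[df["success"]].dropna(subset=["aligned_x", "aligned_y"])
    rows = []
    for dist, grp in ok.groupby("distance", sort=True):
        endpoints = grp[["aligned_x", "aligned_y"]].to_numpy()
        mt = grp["primary_mt"] + grp["correction"] + grp["dwell"]
        row = {
            "distance": float(dist),
            "n_trials": len(grp),
            "median_mt": float(mt.median()),
            "median_peak_speed": float(grp["peak_speed"].median()),
            "sd_peak_speed": float(grp["peak_speed"].std(ddof=1)),
            "mean_extent": float(grp["extent_at_pe"].mean()),
            "effective_id": effective_id(float(grp["extent_at_pe"].mean()), endpoints),
            "aspect_ratio": error_ellipse(endpoints, coverage).aspect_ratio,
        }
        rows.append(row)
    return pd.DataFrame(rows)
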
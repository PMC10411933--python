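"""Session file format: plain tab-separated text with a versioned header.

A session file is inspectable with any text tool and round-trips losslessly.
Layout::

    #aimkin-session 1
    #header\t{json}
    [trials]
    <tsv with header row>
    [samples]
    <tsv>
    [events]
    <tsv>
    [ground_truth]      (optional)
    <tsv>

Reading validates the structural invariants — time-sorted samples and
events per trial, cursor positions reproduced by the cumulative gain-scaled
deltas to within 1e-9 au, no orphan sample/event rows, and every successful
trial's click landing inside the target — and raises
:class:`SessionFormatError` naming the offending line.
"""

from __future__ import annotations

import io
import json
import math

import numpy as np
import pandas as pd

from .records import EVENT_NAMES, GroundTruth, Session, TrialRecord

__all__ = ["SessionFormatError", "write_session", "read_session", "session_frames"]

FORMAT_NAME = "#aimkin-session"
FORMAT_VERSION = 1

_TRIAL_COLS = [
    "trial_id", "context", "staircase_id", "time_limit", "round_index",
    "cycle_index", "target_distance", "target_angle", "start_x", "start_y",
    "target_x", "target_y", "success", "n_submovements",
]
_SAMPLE_COLS = ["trial_id", "t_ms", "dx", "dy", "x", "y"]
_EVENT_COLS = ["trial_id", "t_ms", "event"]
_GT_COLS = ["trial_id", "true_onset", "true_primary_end", "true_last_entry", "true_click"]


class SessionFormatError(ValueError):
    """Malformed or internally inconsistent session file."""


def _fmt(v) -> str:
    if v is None:
        return ""
    if isinstance(v, bool) or isinstance(v, np.bool_):
        return "1" if v else "0"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def session_frames(session: Session) -> dict[str, pd.DataFrame]:
    """The session's trials/samples/events (and ground truth, if any) as
    tidy DataFrames — the in-memory mirror of the file sections."""
    trials, samples, events, gts = [], [], [], []
    for tr in session.trials:
        trials.append(
            {
                "trial_id": tr.trial_id,
                "context": tr.context,
                "staircase_id": tr.staircase_id,
                "time_limit": tr.time_limit,
                "round_index": tr.round_index,
                "cycle_index": tr.cycle_index,
                "target_distance": tr.target_distance,
                "target_angle": tr.target_angle,
                "start_x": tr.start_pos[0],
                "start_y": tr.start_pos[1],
                "target_x": tr.target_pos[0],
                "target_y": tr.target_pos[1],
                "success": tr.success,
                "n_submovements": tr.n_submovements,
            }
        )
        samples.append(
            pd.DataFrame(
                {
                    "trial_id": tr.trial_id,
                    "t_ms": tr.t_ms,
                    "dx": tr.dx,
                    "dy": tr.dy,
                    "x": tr.x,
                    "y": tr.y,
                }
            )
        )
        events.extend({"trial_id": tr.trial_id, "t_ms": t, "event": name} for t, name in tr.events)
        if tr.ground_truth is not None:
            gt = tr.ground_truth
            gts.append(
                {
                    "trial_id": tr.trial_id,
                    "true_onset": gt.true_onset,
                    "true_primary_end": gt.true_primary_end,
                    "true_last_entry": gt.true_last_entry,
                    "true_click": gt.true_click,
                }
            )
    out = {
        "trials": pd.DataFrame(trials, columns=_TRIAL_COLS),
        "samples": pd.concat(samples, ignore_index=True) if samples else pd.DataFrame(columns=_SAMPLE_COLS),
        "events": pd.DataFrame(events, columns=_EVENT_COLS),
    }
    if gts:
        out["ground_truth"] = pd.DataFrame(gts, columns=_GT_COLS)
    return out


def write_session(session: Session, path) -> None:
    """Write a session to ``path`` (deterministic: same session, same bytes)."""
    frames = session_frames(session)
    header = {
        "format_version": session.format_version,
        "experiment": session.experiment,
        "scene": session.scene,
        "device": session.device,
        "seed": session.seed,
    }
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"{FORMAT_NAME} {FORMAT_VERSION}\n")
        fh.write("#header\t" + json.dumps(header, sort_keys=True) + "\n")
        for name, df in frames.items():
            fh.write(f"[{name}]\n")
            fh.write("\t".join(df.columns) + "\n")
            for row in df.itertuples(index=False):
                fh.write("\t".join(_fmt(v) for v in row) + "\n")


def _parse_sections(lines: list[str]) -> tuple[dict, dict[str, tuple[int, pd.DataFrame]]]:
    if not lines or not lines[0].startswith(FORMAT_NAME):
        raise SessionFormatError(f"line 1: not a session file (missing {FORMAT_NAME} magic)")
    header = {}
    sections: dict[str, tuple[int, pd.DataFrame]] = {}
    current: str | None = None
    buf: list[str] = []
    buf_start = 0

    def flush() -> None:
        if current is None:
            return
        if not buf:
            raise SessionFormatError(f"line {buf_start}: section [{current}] has no header row")
        df = pd.read_csv(
            io.StringIO("\n".join(buf)),
            sep="\t",
            dtype={"event": str, "context": str},
            float_precision="round_trip",
        )
        sections[current] = (buf_start, df)

    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if lineno == 1:
            continue
        if line.startswith("#header"):
            try:
                header = json.loads(line.split("\t", 1)[1])
            except (IndexError, json.JSONDecodeError) as exc:
                raise SessionFormatError(f"line {lineno}: bad header json ({exc})") from exc
            continue
        if line.startswith("[") and line.endswith("]"):
            flush()
            current = line[1:-1]
            buf = []
            buf_start = lineno + 1
            continue
        if not line:
            continue
        if current is None:
            raise SessionFormatError(f"line {lineno}: data outside any section")
        buf.append(line)
    flush()
    return header, sections


def read_session(path) -> Session:
    """Read and validate a session file."""
    with open(path, encoding="utf-8") as fh:
        lines = fh.readlines()
    header, sections = _parse_sections(lines)

    gain = float(header.get("scene", {}).get("gain", 1.0))
    target_diameter = float(header.get("scene", {}).get("target_diameter", 0.2))

    if "trials" not in sections:
        # header-only file: a valid empty session
        return Session(
            experiment=header.get("experiment", "exp1"),
            trials=[],
            scene=header.get("scene", {}),
            device=header.get("device", "mouse"),
            seed=header.get("seed"),
            format_version=int(header.get("format_version", FORMAT_VERSION)),
        )

    trials_line, trials_df = sections["trials"]
    samples_line, samples_df = sections.get("samples", (0, pd.DataFrame(columns=_SAMPLE_COLS)))
    events_line, events_df = sections.get("events", (0, pd.DataFrame(columns=_EVENT_COLS)))
    gt_df = sections.get("ground_truth", (0, None))[1]

    known_ids = set(trials_df["trial_id"].tolist())
    for name, (start_line, df) in (("samples", (samples_line, samples_df)), ("events", (events_line, events_df))):
        orphans = ~df["trial_id"].isin(known_ids)
        if orphans.any():
            row = int(np.nonzero(orphans.to_numpy())[0][0])
            raise SessionFormatError(
                f"line {start_line + 1 + row}: [{name}] row references unknown "
                f"trial {df['trial_id'].iloc[row]}"
            )
    bad_events = ~events_df["event"].isin(EVENT_NAMES)
    if bad_events.any():
        row = int(np.nonzero(bad_events.to_numpy())[0][0])
        raise SessionFormatError(
            f"line {events_line + 1 + row}: unknown event {events_df['event'].iloc[row]!r}"
        )

    gt_by_trial = {}
    if gt_df is not None:
        for r in gt_df.itertuples(index=False):
            gt_by_trial[int(r.trial_id)] = GroundTruth(
                r.true_onset, r.true_primary_end, r.true_last_entry, r.true_click
            )

    trials: list[TrialRecord] = []
    sample_groups = dict(iter(samples_df.groupby("trial_id", sort=False)))
    event_groups = dict(iter(events_df.groupby("trial_id", sort=False)))
    for r in trials_df.itertuples(index=False):
        tid = int(r.trial_id)
        smp = sample_groups.get(tid, samples_df.iloc[0:0])
        evt = event_groups.get(tid, events_df.iloc[0:0])
        t = smp["t_ms"].to_numpy(dtype=float)
        if t.size and np.any(np.diff(t) <= 0):
            k = int(np.argmax(np.diff(t) <= 0)) + 1
            row = int(smp.index[k])
            raise SessionFormatError(
                f"line {samples_line + 1 + row}: trial {tid} sample timestamps "
                "not strictly increasing"
            )
        et = evt["t_ms"].to_numpy(dtype=float)
        if et.size and np.any(np.diff(et) < 0):
            k = int(np.argmax(np.diff(et) < 0)) + 1
            row = int(evt.index[k])
            raise SessionFormatError(
                f"line {events_line + 1 + row}: trial {tid} events not time-sorted"
            )
        x = smp["x"].to_numpy(dtype=float)
        y = smp["y"].to_numpy(dtype=float)
        dx = smp["dx"].to_numpy(dtype=float)
        dy = smp["dy"].to_numpy(dtype=float)
        if t.size:
            rx = x[0] + gain * np.cumsum(dx) - gain * dx[0]
            ry = y[0] + gain * np.cumsum(dy) - gain * dy[0]
            err = max(np.abs(rx - x).max(), np.abs(ry - y).max())
            if err > 1e-9:
                raise SessionFormatError(
                    f"trial {tid}: cumulative deltas diverge from cursor "
                    f"positions by {err:.2e} au (> 1e-9)"
                )
        success = bool(r.success)
        if success and t.size:
            click_t = et[evt["event"].to_numpy() == "click"]
            if not click_t.size:
                raise SessionFormatError(f"trial {tid}: successful trial has no click event")
            k = int(np.searchsorted(t, click_t[-1], side="right")) - 1
            d = math.hypot(x[k] - float(r.target_x), y[k] - float(r.target_y))
            if d > target_diameter / 2.0 + 1e-9:
                raise SessionFormatError(
                    f"trial {tid}: successful click at {click_t[-1]} ms lies "
                    f"{d:.3f} au from the target center (outside the target)"
                )

        def _opt(v):
            return None if (v is None or (isinstance(v, float) and math.isnan(v))) else v

        trials.append(
            TrialRecord(
                trial_id=tid,
                context=str(r.context),
                target_distance=float(r.target_distance),
                target_angle=float(r.target_angle),
                start_pos=(float(r.start_x), float(r.start_y)),
                target_pos=(float(r.target_x), float(r.target_y)),
                t_ms=t,
                dx=dx,
                dy=dy,
                x=x,
                y=y,
                events=[(float(tt), str(nm)) for tt, nm in zip(et, evt["event"])],
                success=success,
                staircase_id=_opt(r.staircase_id if isinstance(r.staircase_id, str) else None),
                time_limit=_opt(float(r.time_limit) if pd.notna(r.time_limit) else None),
                round_index=int(r.round_index) if pd.notna(r.round_index) else None,
                cycle_index=int(r.cycle_index) if pd.notna(r.cycle_index) else None,
                n_submovements=int(r.n_submovements),
                ground_truth=gt_by_trial.get(tid),
            )
        )
    return Session(
        experiment=header.get("experiment", "exp1"),
        trials=trials,
        scene=header.get("scene", {}),
        device=header.get("device", "mouse"),
        seed=header.get("seed"),
        format_version=int(header.get("format_version", FORMAT_VERSION)),
    )
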
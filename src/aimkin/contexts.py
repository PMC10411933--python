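"""Workspace geometry and the Point/Look visuomotor contexts.

The task presents a circular target plane viewed either in a *Point* context
(mouse deltas translate a cursor across a static scene, desktop-style) or a
*Look* context (mouse deltas pan/tilt a first-person camera while the cursor
stays at screen center, FPS "Mouselook").

The two contexts are equated constructively: a single *virtual cursor* lives
in plane coordinates and is driven by the same gain-scaled mouse deltas in
both contexts.  Point renders the cursor at its plane position; Look renders
the camera pose whose central ray intersects the plane at the cursor.  By
construction an identical delta stream yields an identical analysis-space
trajectory in either context, so all downstream kinematic analysis is
context-agnostic and the context label matters only for rendering and for
the synthetic performer's latency penalties.

Units: lengths are in "au" (arbitrary Unity units; the scene height is 4 au),
angles in degrees.  Plane coordinates have their origin at the plane center,
x rightward, y upward; 0 deg points rightward and angles increase
counterclockwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SceneConfig",
    "CameraPose",
    "GeometryError",
    "point_step",
    "look_pose_for_cursor",
    "cursor_for_look_pose",
    "effective_cursor_path",
    "snap_to_start",
]

#: Vertical field of view (degrees) of the Look camera.  The default plane
#: distance is chosen so the 4-au scene height exactly subtends this FOV
#: (the Unity default of 60 deg), i.e. distance = (height/2) / tan(fov/2).
DEFAULT_FOV_DEG = 60.0


def _default_plane_distance(scene_height: float = 4.0, fov_deg: float = DEFAULT_FOV_DEG) -> float:
    return (scene_height / 2.0) / math.tan(math.radians(fov_deg / 2.0))


class GeometryError(ValueError):
    """A camera pose or geometric construction is out of range."""


@dataclass(frozen=True)
class SceneConfig:
    """Static geometry of the shooting scene.

    All lengths in au.  ``gain`` converts raw device counts to au of virtual
    cursor motion (1.0 means deltas are already expressed in normalized
    device units; the in-game sensitivity calibration maps onto this knob).
    """

    scene_height: float = 4.0
    plane_diameter: float = 3.0
    start_diameter: float = 0.1
    cursor_diameter: float = 0.15
    target_diameter: float = 0.2
    snap_radius: float = 0.05
    plane_distance: float = field(default_factory=_default_plane_distance)
    gain: float = 1.0

    def __post_init__(self) -> None:
        lengths = {
            "scene_height": self.scene_height,
            "plane_diameter": self.plane_diameter,
            "start_diameter": self.start_diameter,
            "cursor_diameter": self.cursor_diameter,
            "target_diameter": self.target_diameter,
            "snap_radius": self.snap_radius,
            "plane_distance": self.plane_distance,
            "gain": self.gain,
        }
        for name, value in lengths.items():
            if not (np.isfinite(value) and value > 0):
                raise ValueError(f"SceneConfig.{name} must be finite and > 0, got {value!r}")
        if not self.target_diameter < self.plane_diameter:
            raise ValueError("target_diameter must be smaller than plane_diameter")
        if not self.snap_radius < self.start_diameter:
            raise ValueError("snap_radius must be smaller than start_diameter")

    @property
    def target_radius(self) -> float:
        return self.target_diameter / 2.0

    def to_dict(self) -> dict:
        return {
            "scene_height": self.scene_height,
            "plane_diameter": self.plane_diameter,
            "start_diameter": self.start_diameter,
            "cursor_diameter": self.cursor_diameter,
            "target_diameter": self.target_diameter,
            "snap_radius": self.snap_radius,
            "plane_distance": self.plane_distance,
            "gain": self.gain,
        }


@dataclass(frozen=True)
class CameraPose:
    """Look-camera orientation; yaw about the vertical axis, pitch about the
    horizontal, both in degrees and constrained to (-90, 90)."""

    yaw: float
    pitch: float

    def __post_init__(self) -> None:
        if not (abs(self.yaw) < 90.0 and abs(self.pitch) < 90.0):
            raise GeometryError(f"camera pose out of range: yaw={self.yaw}, pitch={self.pitch}")


def point_step(cursor, delta, cfg: SceneConfig) -> np.ndarray:
    """Advance the Point cursor by one gain-scaled device delta (no clamping)."""
    cursor = np.asarray(cursor, dtype=float)
    delta = np.asarray(delta, dtype=float)
    if not np.all(np.isfinite(delta)):
        raise ValueError(f"non-finite delta: {delta!r}")
    return cursor + cfg.gain * delta


def look_pose_for_cursor(virtual_cursor, cfg: SceneConfig) -> CameraPose:
    """Camera pose whose central ray intersects the plane at ``virtual_cursor``.

    yaw = arctan(x / d), pitch = arctan(y / d) with d the camera-to-plane
    distance.  The pan and tilt are applied in independent plane-coordinate
    axes, which is exactly invertible (see :func:`cursor_for_look_pose`).
    """
    x, y = (float(v) for v in np.asarray(virtual_cursor, dtype=float))
    if not (math.isfinite(x) and math.isfinite(y)):
        raise GeometryError(f"non-finite cursor: ({x}, {y})")
    return CameraPose(
        yaw=math.degrees(math.atan(x / cfg.plane_distance)),
        pitch=math.degrees(math.atan(y / cfg.plane_distance)),
    )


def cursor_for_look_pose(pose: CameraPose, cfg: SceneConfig) -> np.ndarray:
    """Ray-plane intersection: plane point the camera's central ray hits."""
    return np.array(
        [
            cfg.plane_distance * math.tan(math.radians(pose.yaw)),
            cfg.plane_distance * math.tan(math.radians(pose.pitch)),
        ]
    )


def effective_cursor_path(t_ms, deltas, context: str, cfg: SceneConfig, start=(0.0, 0.0)) -> np.ndarray:
    """Map a timestamped delta stream to the analysis-space cursor path.

    Returns an ``(n + 1, 2)`` array beginning at ``start``.  The result is
    identical for both contexts by construction: Look is a rendering
    transform of the same virtual cursor, so the context argument is only
    validated, never branched on.
    """
    if context not in ("point", "look"):
        raise ValueError(f"unknown context {context!r}")
    t_ms = np.asarray(t_ms, dtype=float)
    deltas = np.asarray(deltas, dtype=float).reshape(-1, 2)
    if t_ms.shape[0] != deltas.shape[0]:
        raise ValueError("timestamps and deltas must have equal length")
    if t_ms.size and np.any(np.diff(t_ms) <= 0):
        bad = int(np.argmax(np.diff(t_ms) <= 0)) + 1
        raise ValueError(f"timestamps not strictly increasing at sample {bad}")
    start = np.asarray(start, dtype=float)
    path = np.empty((deltas.shape[0] + 1, 2))
    path[0] = start
    if deltas.shape[0]:
        path[1:] = start + np.cumsum(cfg.gain * deltas, axis=0)
    return path


def snap_to_start(cursor, cfg: SceneConfig) -> np.ndarray:
    """Homing-phase auto-aim: snap to the plane center when within the snap
    radius (boundary inclusive: distance == snap_radius snaps)."""
    cursor = np.asarray(cursor, dtype=float)
    if math.hypot(cursor[0], cursor[1]) <= cfg.snap_radius:
        return np.zeros(2)
    return cursor
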
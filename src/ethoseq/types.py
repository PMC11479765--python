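"""Core domain types for arena recordings of group-housed mice.

Conventions used throughout the package:

* frames are 0-based integers; all intervals are half-open ``[start, end)``,
  so a duration in seconds is ``(end - start) / fps``;
* coordinates are centimetres with the origin at the arena's lower-left
  corner, x pointing east and y pointing north;
* ellipse orientations (headings) are radians in ``(-pi, pi]``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "ArenaSpec",
    "MouseInfo",
    "FramePose",
    "Trajectory",
    "BehaviorEvent",
    "RecordingBundle",
    "AggressionSummary",
    "SocialInteraction",
    "AGGRESSIVE_LABELS",
    "EVENT_LABELS",
]

#: Labels with discernible aggressor/aggressed roles.
AGGRESSIVE_LABELS = frozenset({"chase", "flee"})

#: Full behavioral repertoire handled by the event table.
EVENT_LABELS = frozenset({"chase", "flee", "walk", "investigate", "fight"})


@dataclass(frozen=True)
class ArenaSpec:
    """Geometry and frame rate of the recording arena.

    The standard arena is a 76.2 x 76.2 cm square recorded at 30 frames/s;
    a cylindrical arena (diameter 68.6 cm) is also supported.
    """

    shape: str = "rectangle"  # "rectangle" | "circle"
    width_cm: float = 76.2
    height_cm: float = 76.2
    diameter_cm: Optional[float] = None
    fps: float = 30.0

    def __post_init__(self) -> None:
        if self.shape not in ("rectangle", "circle"):
            raise ValueError(f"unknown arena shape {self.shape!r}")
        if self.shape == "rectangle":
            if self.width_cm <= 0 or self.height_cm <= 0:
                raise ValueError("arena dimensions must be positive")
        else:
            if not self.diameter_cm or self.diameter_cm <= 0:
                raise ValueError("circular arena needs a positive diameter_cm")
        if self.fps <= 0:
            raise ValueError("fps must be positive")

    @property
    def bounds(self) -> tuple[float, float]:
        """(x extent, y extent) of the bounding box, cm."""
        if self.shape == "rectangle":
            return (self.width_cm, self.height_cm)
        return (self.diameter_cm, self.diameter_cm)

    def contains(self, x: float, y: float, tol_cm: float = 1.0) -> bool:
        """Whether a point lies inside the arena (with wall tolerance)."""
        if self.shape == "rectangle":
            return (-tol_cm <= x <= self.width_cm + tol_cm) and (
                -tol_cm <= y <= self.height_cm + tol_cm
            )
        r = self.diameter_cm / 2.0
        return (x - r) ** 2 + (y - r) ** 2 <= (r + tol_cm) ** 2


@dataclass(frozen=True)
class MouseInfo:
    mouse_id: str
    sex: str  # "M" | "F"

    def __post_init__(self) -> None:
        if self.sex not in ("M", "F"):
            raise ValueError(f"sex must be 'M' or 'F', got {self.sex!r}")


@dataclass(frozen=True)
class FramePose:
    """One mouse's fitted body ellipse and nose position at a single frame."""

    mouse_id: str
    frame: int
    x_cm: float
    y_cm: float
    theta_rad: float
    a_cm: float
    b_cm: float
    nose_x_cm: float
    nose_y_cm: float

    def __post_init__(self) -> None:
        if not (self.a_cm >= self.b_cm > 0):
            raise ValueError("ellipse axes must satisfy a >= b > 0")


class Trajectory:
    """Dense, frame-indexed pose track of one mouse.

    Stores the fitted body ellipse (centroid, orientation, semi-axes) and the
    nose position at every frame as parallel numpy arrays.
    """

    __slots__ = ("mouse_id", "frames", "x", "y", "theta", "a", "b",
                 "nose_x", "nose_y", "fps", "_speed")

    def __init__(self, mouse_id, frames, x, y, theta, a, b, nose_x, nose_y,
                 fps=30.0):
        self.mouse_id = str(mouse_id)
        self.frames = np.asarray(frames, dtype=np.int64)
        self.x = np.asarray(x, dtype=float)
        self.y = np.asarray(y, dtype=float)
        self.theta = np.asarray(theta, dtype=float)
        self.a = np.asarray(a, dtype=float)
        self.b = np.asarray(b, dtype=float)
        self.nose_x = np.asarray(nose_x, dtype=float)
        self.nose_y = np.asarray(nose_y, dtype=float)
        self.fps = float(fps)
        self._speed = None
        self.validate()

    def __len__(self) -> int:
        return len(self.frames)

    def validate(self) -> None:
        n = len(self.frames)
        for name in ("x", "y", "theta", "a", "b", "nose_x", "nose_y"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"column {name} has wrong length")
        if n:
            gaps = np.nonzero(np.diff(self.frames) != 1)[0]
            if gaps.size:
                missing = [int(self.frames[g]) + 1 for g in gaps[:5]]
                raise ValueError(
                    f"non-contiguous frames for mouse {self.mouse_id}: "
                    f"gap(s) after frame(s) {missing}"
                )
            if np.any(self.b <= 0) or np.any(self.a < self.b):
                raise ValueError(
                    f"mouse {self.mouse_id}: ellipse axes must satisfy a >= b > 0"
                )

    @property
    def start_frame(self) -> int:
        return int(self.frames[0])

    def index_of(self, frame: int) -> int:
        i = int(frame) - self.start_frame
        if i < 0 or i >= len(self):
            raise IndexError(f"frame {frame} outside trajectory of {self.mouse_id}")
        return i

    def pose_at(self, frame: int) -> FramePose:
        i = self.index_of(frame)
        return FramePose(
            mouse_id=self.mouse_id, frame=int(frame),
            x_cm=float(self.x[i]), y_cm=float(self.y[i]),
            theta_rad=float(self.theta[i]),
            a_cm=float(self.a[i]), b_cm=float(self.b[i]),
            nose_x_cm=float(self.nose_x[i]), nose_y_cm=float(self.nose_y[i]),
        )

    @property
    def speed(self) -> np.ndarray:
        """Per-frame instantaneous speed (cm/s); lazy, cached."""
        if self._speed is None:
            from .kinematics import compute_speed

            self._speed = compute_speed(self, self.fps)
        return self._speed


@dataclass
class BehaviorEvent:
    """A labeled behavioral interval with optional actor/recipient roles.

    For chase and flee the aggressor/aggressed roles are derived from the
    actor: the chasing male (or the one being fled from) is the aggressor,
    the chased (or fleeing) male the aggressed.
    """

    label: str
    actor_id: str
    recipient_id: Optional[str]
    start_frame: int
    end_frame: int
    confidence: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label not in EVENT_LABELS:
            raise ValueError(f"unknown behavior label {self.label!r}")
        if self.end_frame <= self.start_frame:
            raise ValueError(
                f"end_frame ({self.end_frame}) must exceed start_frame "
                f"({self.start_frame})"
            )
        if self.recipient_id is not None and self.actor_id == self.recipient_id:
            raise ValueError("actor and recipient must differ")
        if self.label in ("chase", "flee", "investigate", "fight") and (
            self.recipient_id is None
        ):
            raise ValueError(f"{self.label} requires a recipient_id")

    @property
    def aggressor_id(self) -> Optional[str]:
        if self.label == "chase":
            return self.actor_id
        if self.label == "flee":
            return self.recipient_id
        return None

    @property
    def aggressed_id(self) -> Optional[str]:
        if self.label == "chase":
            return self.recipient_id
        if self.label == "flee":
            return self.actor_id
        return None

    @property
    def is_aggressive(self) -> bool:
        return self.label in AGGRESSIVE_LABELS

    def duration_frames(self) -> int:
        return self.end_frame - self.start_frame

    def duration_s(self, fps: float) -> float:
        return self.duration_frames() / fps


@dataclass
class RecordingBundle:
    """One recording: arena, mouse roster, trajectories and labeled events."""

    arena: ArenaSpec
    mice: list[MouseInfo]
    trajectories: dict[str, Trajectory]
    events: list[BehaviorEvent] = field(default_factory=list)
    recording_id: str = "rec"

    def __post_init__(self) -> None:
        ids = [m.mouse_id for m in self.mice]
        if len(set(ids)) != len(ids):
            raise ValueError("mouse ids must be unique within a recording")
        lengths = {len(t) for t in self.trajectories.values()}
        if len(lengths) > 1:
            raise ValueError("co-recorded trajectories must have equal length")
        known = set(ids) | set(self.trajectories)
        for ev in self.events:
            for mid in (ev.actor_id, ev.recipient_id):
                if mid is not None and mid not in known:
                    raise ValueError(
                        f"event references unknown mouse {mid!r}"
                    )

    @property
    def n_frames(self) -> int:
        if not self.trajectories:
            return 0
        return len(next(iter(self.trajectories.values())))

    def males(self) -> list[str]:
        return [m.mouse_id for m in self.mice if m.sex == "M"]

    def females(self) -> list[str]:
        return [m.mouse_id for m in self.mice if m.sex == "F"]

    def sex_of(self, mouse_id: str) -> str:
        for m in self.mice:
            if m.mouse_id == mouse_id:
                return m.sex
        raise KeyError(mouse_id)


@dataclass
class AggressionSummary:
    """Per-recording asymmetry in aggressive behavior between the two males.

    ``score = (n_male1 - n_male2) / (n_male1 + n_male2)`` where ``n`` counts
    the events in which each male acted as the aggressor; the chi-square
    tests the counts against an equal 50/50 expectation.
    """

    counts: dict[str, int]
    aggression_score: Optional[float]
    more_aggressive_id: Optional[str]
    chi_square_stat: Optional[float]
    chi_square_p: Optional[float]
    defined: bool = True


@dataclass
class SocialInteraction:
    """An opposite-sex social-ellipse overlap bout lasting >= 6 frames."""

    male_id: str
    female_id: str
    start_frame: int
    end_frame: int
    fps: float = 30.0
    initiator: str = "undetermined"  # male | female | mutual | undetermined

    def __post_init__(self) -> None:
        if self.end_frame <= self.start_frame:
            raise ValueError("SI end_frame must exceed start_frame")

    @property
    def duration_s(self) -> float:
        return (self.end_frame - self.start_frame) / self.fps
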
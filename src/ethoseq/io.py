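"""Reading and writing the plain-text table formats used by the pipeline.

Pose tables and event tables are UTF-8 CSV files with a header row
(optionally gzip-compressed; pandas handles the compression transparently).
A small JSON sidecar carries the arena geometry and mouse sexes.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .types import (
    ArenaSpec,
    BehaviorEvent,
    MouseInfo,
    RecordingBundle,
    SocialInteraction,
    Trajectory,
)

POSE_COLUMNS = [
    "recording_id", "mouse_id", "frame", "x_cm", "y_cm", "theta_rad",
    "a_cm", "b_cm", "nose_x_cm", "nose_y_cm",
]

EVENT_COLUMNS = [
    "label", "actor_id", "recipient_id", "start_frame", "end_frame",
    "confidence",
]


class FormatError(ValueError):
    """Raised when a table is missing required columns or malformed."""


def _require_columns(df: pd.DataFrame, required: list[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{what} is missing column(s): {', '.join(missing)}")


def read_pose_table(path, arena: ArenaSpec,
                    mice: Optional[list[MouseInfo]] = None) -> RecordingBundle:
    """Read a pose CSV into a :class:`RecordingBundle` (trajectories only).

    Each row is one mouse at one frame. Trajectories are grouped per mouse,
    frame-sorted and validated (contiguous frames, a >= b > 0).
    """
    df = pd.read_csv(path)
    _require_columns(df, POSE_COLUMNS, "pose table")
    trajectories: dict[str, Trajectory] = {}
    recording_id = "rec"
    if len(df):
        recording_id = str(df["recording_id"].iloc[0])
        for mouse_id, grp in df.groupby("mouse_id", sort=True):
            grp = grp.sort_values("frame")
            trajectories[str(mouse_id)] = Trajectory(
                mouse_id=str(mouse_id),
                frames=grp["frame"].to_numpy(),
                x=grp["x_cm"].to_numpy(),
                y=grp["y_cm"].to_numpy(),
                theta=grp["theta_rad"].to_numpy(),
                a=grp["a_cm"].to_numpy(),
                b=grp["b_cm"].to_numpy(),
                nose_x=grp["nose_x_cm"].to_numpy(),
                nose_y=grp["nose_y_cm"].to_numpy(),
                fps=arena.fps,
            )
    if mice is None:
        mice = [MouseInfo(mid, "M") for mid in sorted(trajectories)]
    return RecordingBundle(
        arena=arena, mice=mice, trajectories=trajectories,
        events=[], recording_id=recording_id,
    )


def write_pose_table(bundle: RecordingBundle, path) -> None:
    frames = []
    for mid in sorted(bundle.trajectories):
        t = bundle.trajectories[mid]
        frames.append(pd.DataFrame({
            "recording_id": bundle.recording_id,
            "mouse_id": t.mouse_id,
            "frame": t.frames,
            "x_cm": t.x,
            "y_cm": t.y,
            "theta_rad": t.theta,
            "a_cm": t.a,
            "b_cm": t.b,
            "nose_x_cm": t.nose_x,
            "nose_y_cm": t.nose_y,
        }))
    if frames:
        out = pd.concat(frames, ignore_index=True)
    else:
        out = pd.DataFrame(columns=POSE_COLUMNS)
    out.to_csv(path, index=False)


def read_event_table(path) -> list[BehaviorEvent]:
    """Read a behavior-event CSV; derives roles and sorts by start frame."""
    df = pd.read_csv(path)
    _require_columns(df, EVENT_COLUMNS, "event table")
    events = []
    for row in df.itertuples(index=False):
        recipient = row.recipient_id
        if recipient is None or (isinstance(recipient, float) and np.isnan(recipient)) \
                or recipient in ("", "-", "−"):
            recipient = None
        conf = row.confidence
        if conf is not None and isinstance(conf, float) and np.isnan(conf):
            conf = None
        events.append(BehaviorEvent(
            label=str(row.label),
            actor_id=str(row.actor_id),
            recipient_id=None if recipient is None else str(recipient),
            start_frame=int(row.start_frame),
            end_frame=int(row.end_frame),
            confidence=None if conf is None else float(conf),
        ))
    events.sort(key=lambda e: (e.start_frame, e.end_frame))
    return events


def write_event_table(events: Iterable[BehaviorEvent], path) -> None:
    rows = [{
        "label": e.label,
        "actor_id": e.actor_id,
        "recipient_id": e.recipient_id if e.recipient_id is not None else "-",
        "start_frame": e.start_frame,
        "end_frame": e.end_frame,
        "confidence": e.confidence,
    } for e in events]
    pd.DataFrame(rows, columns=EVENT_COLUMNS).to_csv(path, index=False)


def write_interactions_table(interactions: Iterable[SocialInteraction], path,
                             recording_id: str = "rec") -> None:
    rows = [{
        "recording_id": recording_id,
        "male_id": si.male_id,
        "female_id": si.female_id,
        "start_frame": si.start_frame,
        "end_frame": si.end_frame,
        "duration_s": si.duration_s,
        "initiator": si.initiator,
    } for si in interactions]
    cols = ["recording_id", "male_id", "female_id", "start_frame",
            "end_frame", "duration_s", "initiator"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def write_sidecar(bundle: RecordingBundle, path) -> None:
    """Write the JSON sidecar with arena geometry and mouse sexes."""
    arena = bundle.arena
    meta = {
        "recording_id": bundle.recording_id,
        "arena": {
            "shape": arena.shape,
            "width_cm": arena.width_cm,
            "height_cm": arena.height_cm,
            "diameter_cm": arena.diameter_cm,
            "fps": arena.fps,
        },
        "mice": [{"mouse_id": m.mouse_id, "sex": m.sex} for m in bundle.mice],
    }
    Path(path).write_text(json.dumps(meta, indent=2))


def read_sidecar(path) -> tuple[ArenaSpec, list[MouseInfo], str]:
    meta = json.loads(Path(path).read_text())
    a = meta["arena"]
    arena = ArenaSpec(
        shape=a["shape"], width_cm=a["width_cm"], height_cm=a["height_cm"],
        diameter_cm=a.get("diameter_cm"), fps=a["fps"],
    )
    mice = [MouseInfo(m["mouse_id"], m["sex"]) for m in meta["mice"]]
    return arena, mice, meta.get("recording_id", "rec")
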
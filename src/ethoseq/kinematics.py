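"""Per-frame kinematics, exploration coverage, aggression summaries and the
post-hoc refinement filters applied to classifier-labeled behavior events.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .types import (
    AggressionSummary,
    ArenaSpec,
    BehaviorEvent,
    Trajectory,
)

__all__ = [
    "compute_speed",
    "exploration_fraction",
    "aggression_summary",
    "RefinementRule",
    "default_refinement_rules",
    "refine_events",
    "RefinementReport",
]


def compute_speed(trajectory: Trajectory, fps: float) -> np.ndarray:
    """Instantaneous speed (cm/s) from frame-to-frame centroid displacement.

    ``speed[t]`` is the Euclidean displacement from frame ``t-1`` to ``t``
    times ``fps``; ``speed[0]`` is backfilled from ``speed[1]`` so the series
    is total.
    """
    if len(trajectory) < 2:
        raise ValueError("speed needs at least 2 frames")
    dx = np.diff(trajectory.x)
    dy = np.diff(trajectory.y)
    speed = np.empty(len(trajectory))
    speed[1:] = np.hypot(dx, dy) * fps
    speed[0] = speed[1]
    return speed


def exploration_fraction(trajectory: Trajectory, arena: ArenaSpec,
                         bin_area_cm2: float) -> float:
    """Percentage of spatial bins visited by the mouse's centroid.

    Square bins of side ``sqrt(bin_area_cm2)`` tile the arena's bounding box
    starting at the origin. For a rectangular arena every bin overlapping the
    rectangle (including partial edge bins) counts in the denominator; for a
    circular arena a bin counts if its center lies inside the circle.
    """
    side = float(np.sqrt(bin_area_cm2))
    w, h = arena.bounds
    if side > w or side > h:
        raise ValueError("bin side exceeds arena dimensions")
    nx = int(np.ceil(w / side))
    ny = int(np.ceil(h / side))

    if arena.shape == "rectangle":
        eligible = np.ones((nx, ny), dtype=bool)
    else:
        r = arena.diameter_cm / 2.0
        cx = (np.arange(nx) + 0.5) * side
        cy = (np.arange(ny) + 0.5) * side
        eligible = ((cx[:, None] - r) ** 2 + (cy[None, :] - r) ** 2) <= r**2

    ix = np.clip((trajectory.x // side).astype(int), 0, nx - 1)
    iy = np.clip((trajectory.y // side).astype(int), 0, ny - 1)
    visited = np.zeros((nx, ny), dtype=bool)
    visited[ix, iy] = True
    visited &= eligible
    return 100.0 * visited.sum() / eligible.sum()


def aggression_summary(events: Iterable[BehaviorEvent],
                       male_ids: Sequence[str]) -> AggressionSummary:
    """Aggression score and chi-square asymmetry test for a pair of males.

    The score subtracts the second male's aggressor count from the first
    male's and divides by the total; the chi-square is a 1-df goodness-of-fit
    test against equal expected counts.
    """
    if len(male_ids) != 2:
        raise ValueError("aggression_summary expects exactly two male ids")
    counts = {mid: 0 for mid in male_ids}
    for ev in events:
        if ev.is_aggressive and ev.aggressor_id in counts:
            counts[ev.aggressor_id] += 1
    total = sum(counts.values())
    if total == 0:
        return AggressionSummary(
            counts=counts, aggression_score=None, more_aggressive_id=None,
            chi_square_stat=None, chi_square_p=None, defined=False,
        )
    m1, m2 = male_ids
    score = (counts[m1] - counts[m2]) / total
    more = m1 if counts[m1] >= counts[m2] else m2
    if counts[m1] == counts[m2]:
        more = None
    stat, p = stats.chisquare([counts[m1], counts[m2]])
    return AggressionSummary(
        counts=counts, aggression_score=score, more_aggressive_id=more,
        chi_square_stat=float(stat), chi_square_p=float(p),
    )


# ---------------------------------------------------------------------------
# Post-hoc event refinement
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RefinementRule:
    """A named per-event predicate; events failing it are dropped."""

    name: str
    predicate: Callable[[BehaviorEvent, "_EventContext"], bool]


class _EventContext:
    """Distance/speed lookups over the recording's trajectories."""

    def __init__(self, trajectories: dict[str, Trajectory],
                 sexes: Optional[dict[str, str]] = None, fps: float = 30.0):
        self.trajectories = trajectories
        self.sexes = sexes or {}
        self.fps = fps

    def _slice(self, mouse_id: str, start: int, end: int):
        t = self.trajectories[mouse_id]
        i0, i1 = t.index_of(start), t.index_of(end - 1) + 1
        return t, i0, i1

    def mean_distance(self, id1: str, id2: str, start: int, end: int) -> float:
        t1, i0, i1 = self._slice(id1, start, end)
        t2, j0, j1 = self._slice(id2, start, end)
        return float(np.mean(np.hypot(t1.x[i0:i1] - t2.x[j0:j1],
                                      t1.y[i0:i1] - t2.y[j0:j1])))

    def distance_at(self, id1: str, id2: str, frame: int) -> float:
        t1 = self.trajectories[id1]
        t2 = self.trajectories[id2]
        i, j = t1.index_of(frame), t2.index_of(frame)
        return float(np.hypot(t1.x[i] - t2.x[j], t1.y[i] - t2.y[j]))

    def mean_speed(self, mouse_id: str, start: int, end: int) -> float:
        t, i0, i1 = self._slice(mouse_id, start, end)
        return float(np.mean(t.speed[i0:i1]))

    def nearest_female_distance(self, mouse_id: str, frame: int) -> float:
        females = [m for m, s in self.sexes.items() if s == "F"]
        if not females:
            return np.inf
        return min(self.distance_at(mouse_id, f, frame) for f in females)

    def mean_nearest_female_distance(self, mouse_id: str, start: int,
                                     end: int) -> float:
        females = [m for m, s in self.sexes.items() if s == "F"]
        if not females:
            return np.inf
        t, i0, i1 = self._slice(mouse_id, start, end)
        d = np.full(i1 - i0, np.inf)
        for f in females:
            tf, j0, j1 = self._slice(f, start, end)
            d = np.minimum(d, np.hypot(t.x[i0:i1] - tf.x[j0:j1],
                                       t.y[i0:i1] - tf.y[j0:j1]))
        return float(np.mean(d))

    def mean_nearest_any_distance(self, mouse_id: str, start: int,
                                  end: int) -> float:
        others = [m for m in self.trajectories if m != mouse_id]
        if not others:
            return np.inf
        t, i0, i1 = self._slice(mouse_id, start, end)
        d = np.full(i1 - i0, np.inf)
        for o in others:
            to, j0, j1 = self._slice(o, start, end)
            d = np.minimum(d, np.hypot(t.x[i0:i1] - to.x[j0:j1],
                                       t.y[i0:i1] - to.y[j0:j1]))
        return float(np.mean(d))


def _confidence(ev: BehaviorEvent) -> float:
    if ev.confidence is None:
        raise ValueError(
            f"refinement rule requires a confidence score but event "
            f"({ev.label}, frames {ev.start_frame}-{ev.end_frame}) has none"
        )
    return ev.confidence


def default_refinement_rules() -> dict[str, list[RefinementRule]]:
    """Default per-label refinement predicates.

    Thresholds follow the published post-hoc filters: chase needs >6 frames,
    confidence >0.5, mean inter-male distance <30 cm and the chased male's
    nearest female >15 cm away; flee needs >10 frames, confidence >0.7 and
    the closest animal <8 cm; walk needs >20 frames and average score >1;
    investigation is bounded in confidence (> 0.11), actor speed (0.015-0.19)
    and inter-male distance (>0.04 cm); fights need >30 frames, confidence
    >1.5, both males >5 cm from the nearest female at onset, and average
    speed >7.5 cm/s.
    """
    return {
        "chase": [
            RefinementRule("duration_gt_6_frames",
                           lambda e, c: e.duration_frames() > 6),
            RefinementRule("confidence_gt_0.5",
                           lambda e, c: _confidence(e) > 0.5),
            RefinementRule("inter_male_distance_lt_30cm",
                           lambda e, c: c.mean_distance(
                               e.actor_id, e.recipient_id,
                               e.start_frame, e.end_frame) < 30.0),
            RefinementRule("chased_nearest_female_gt_15cm",
                           lambda e, c: c.mean_nearest_female_distance(
                               e.aggressed_id, e.start_frame,
                               e.end_frame) > 15.0),
        ],
        "flee": [
            RefinementRule("duration_gt_10_frames",
                           lambda e, c: e.duration_frames() > 10),
            RefinementRule("confidence_gt_0.7",
                           lambda e, c: _confidence(e) > 0.7),
            RefinementRule("closest_animal_lt_8cm",
                           lambda e, c: c.mean_nearest_any_distance(
                               e.actor_id, e.start_frame,
                               e.end_frame) < 8.0),
        ],
        "walk": [
            RefinementRule("duration_gt_20_frames",
                           lambda e, c: e.duration_frames() > 20),
            RefinementRule("average_score_gt_1",
                           lambda e, c: _confidence(e) > 1.0),
        ],
        "investigate": [
            RefinementRule("confidence_gt_0.11",
                           lambda e, c: _confidence(e) > 0.11),
            RefinementRule("speed_between_0.015_and_0.19",
                           lambda e, c: 0.015 < c.mean_speed(
                               e.actor_id, e.start_frame, e.end_frame) < 0.19),
            RefinementRule("inter_male_distance_gt_0.04cm",
                           lambda e, c: c.mean_distance(
                               e.actor_id, e.recipient_id,
                               e.start_frame, e.end_frame) > 0.04),
        ],
        "fight": [
            RefinementRule("duration_gt_30_frames",
                           lambda e, c: e.duration_frames() > 30),
            RefinementRule("confidence_gt_1.5",
                           lambda e, c: _confidence(e) > 1.5),
            RefinementRule("males_gt_5cm_from_female_at_start",
                           lambda e, c: min(
                               c.nearest_female_distance(e.actor_id,
                                                         e.start_frame),
                               c.nearest_female_distance(e.recipient_id,
                                                         e.start_frame),
                           ) > 5.0),
            RefinementRule("average_speed_gt_7.5",
                           lambda e, c: max(
                               c.mean_speed(e.actor_id, e.start_frame,
                                            e.end_frame),
                               c.mean_speed(e.recipient_id, e.start_frame,
                                            e.end_frame),
                           ) > 7.5),
        ],
    }


@dataclass
class RefinementReport:
    kept: list[BehaviorEvent]
    rejections: dict[str, int] = field(default_factory=dict)


def refine_events(events: Sequence[BehaviorEvent],
                  trajectories: Optional[dict[str, Trajectory]] = None,
                  rules: Optional[dict[str, list[RefinementRule]]] = None,
                  sexes: Optional[dict[str, str]] = None,
                  fps: float = 30.0) -> RefinementReport:
    """Drop events failing any refinement predicate for their label.

    Returns the surviving events (in input order) and per-rule rejection
    counts. An event is rejected by its first failing rule. Labels without
    rules pass through untouched. Idempotent: re-applying to the output is a
    no-op.
    """
    if rules is None:
        rules = default_refinement_rules()
    ctx = _EventContext(trajectories or {}, sexes=sexes, fps=fps)
    kept: list[BehaviorEvent] = []
    rejections: dict[str, int] = {}
    for ev in events:
        failed = None
        for rule in rules.get(ev.label, ()):
            if not rule.predicate(ev, ctx):
                failed = f"{ev.label}:{rule.name}"
                break
        if failed is None:
            kept.append(ev)
        else:
            rejections[failed] = rejections.get(failed, 0) + 1
    return RefinementReport(kept=kept, rejections=rejections)
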
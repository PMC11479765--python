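"""Angular analyses and circular statistics.

Covers the heading-to-partner angle, wrapped orientation differences,
circular median/variance summaries, a permutation-based two-sample Watson
U-squared test, initiator assignment for social interactions, and the
zone-latency control analysis.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import shapely

from .interactions import (
    DEFAULT_EXTENSION_CM,
    SocialEllipse,
    ellipse_boundary,
    social_ellipse,
)
from .types import (
    ArenaSpec,
    BehaviorEvent,
    FramePose,
    SocialInteraction,
    Trajectory,
)

__all__ = [
    "heading_to_target_angle",
    "orientation_difference",
    "CircularSummary",
    "circular_summary",
    "WatsonU2Result",
    "watson_u2",
    "determine_initiator",
    "ZoneSpec",
    "default_zones",
    "zone_latencies",
]

#: Instantaneous speed (cm/s) below which a mouse counts as stationary.
STATIONARY_SPEED_CM_S = 0.023


def heading_to_target_angle(male_pose: FramePose,
                            female_pose: FramePose) -> float:
    """Unsigned angle (rad, [0, pi]) between a male's heading and the vector
    to the female.

    The heading vector v1 runs from the male's centroid to his nose; v2 runs
    from the male's centroid to the female's centroid. The angle is
    ``atan2(|v1 x v2|, v1 . v2)``.
    """
    v1 = np.array([male_pose.nose_x_cm - male_pose.x_cm,
                   male_pose.nose_y_cm - male_pose.y_cm])
    v2 = np.array([female_pose.x_cm - male_pose.x_cm,
                   female_pose.y_cm - male_pose.y_cm])
    if np.allclose(v1, 0.0) or np.allclose(v2, 0.0):
        raise ValueError("zero-length vector in angle computation")
    cross = v1[0] * v2[1] - v1[1] * v2[0]
    dot = float(v1 @ v2)
    return float(np.arctan2(abs(cross), dot))


def orientation_difference(pose1: FramePose, pose2: FramePose) -> float:
    """Signed wrapped difference theta1 - theta2 in (-pi, pi]."""
    d = pose1.theta_rad - pose2.theta_rad
    d = (d + np.pi) % (2.0 * np.pi) - np.pi
    if d == -np.pi:
        d = np.pi
    return float(d)


@dataclass(frozen=True)
class CircularSummary:
    circular_median: float
    circular_variance: float
    n: int


def _wrap(values: np.ndarray) -> np.ndarray:
    return np.mod(np.asarray(values, dtype=float), 2.0 * np.pi)


def circular_summary(values: Sequence[float]) -> CircularSummary:
    """Circular median and variance of a sample of angles.

    The median minimizes the mean arc-length distance to the sample,
    searched over the sample points themselves (ties broken by the smallest
    wrapped angle). Variance is ``1 - R`` with R the mean resultant length.
    """
    theta = _wrap(np.asarray(values, dtype=float))
    if theta.size == 0:
        raise ValueError("empty angle sample")
    r = np.hypot(np.mean(np.cos(theta)), np.mean(np.sin(theta)))
    variance = float(1.0 - r)

    cand = np.unique(theta)
    diff = np.abs(theta[None, :] - cand[:, None])
    arc = np.minimum(diff, 2.0 * np.pi - diff)
    costs = arc.mean(axis=1)
    median = float(cand[int(np.argmin(costs))])
    return CircularSummary(circular_median=median, circular_variance=variance,
                           n=int(theta.size))


@dataclass(frozen=True)
class WatsonU2Result:
    u2_statistic: float
    p_value: float
    n1: int
    n2: int
    n_permutations: int


def _watson_u2_statistic(pooled: np.ndarray, labels: np.ndarray,
                         n1: int, n2: int) -> float:
    # d_k = F1 - F2 tracked over the pooled circular order; the variance
    # form makes the statistic invariant under joint rotation.
    step = np.where(labels, 1.0 / n1, -1.0 / n2)
    d = np.cumsum(step)
    n = d.size
    return float(n1 * n2 / n**2 * (np.sum(d * d) - np.sum(d) ** 2 / n))


def watson_u2(sample1: Sequence[float], sample2: Sequence[float],
              n_permutations: int = 999,
              seed: Optional[int] = None) -> WatsonU2Result:
    """Two-sample Watson U-squared test for circular distributions.

    The statistic is computed from the two empirical CDFs on the pooled
    circular ranks; significance comes from random permutations of the
    pooled labels, with ``p = (1 + #{U2_perm >= U2_obs}) / (1 + n_perm)``.
    """
    s1 = _wrap(np.asarray(sample1, dtype=float))
    s2 = _wrap(np.asarray(sample2, dtype=float))
    if s1.size < 5 or s2.size < 5:
        raise ValueError("watson_u2 requires at least 5 angles per sample")
    pooled = np.concatenate([s1, s2])
    labels = np.concatenate([np.ones(s1.size, bool), np.zeros(s2.size, bool)])
    order = np.argsort(pooled, kind="mergesort")
    pooled, labels = pooled[order], labels[order]
    u2_obs = _watson_u2_statistic(pooled, labels, s1.size, s2.size)

    rng = np.random.default_rng(seed)
    exceed = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if _watson_u2_statistic(pooled, lab, s1.size, s2.size) >= u2_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + n_permutations)
    return WatsonU2Result(u2_statistic=u2_obs, p_value=p, n1=int(s1.size),
                          n2=int(s2.size), n_permutations=n_permutations)


# ---------------------------------------------------------------------------
# Initiator assignment
# ---------------------------------------------------------------------------

def _front_half_polygon(pose: FramePose, extension_cm: float):
    """Half of the social ellipse on the nose side of the minor axis."""
    e = social_ellipse(pose, extension_cm)
    ux, uy = np.cos(e.orientation), np.sin(e.orientation)
    forward = (pose.nose_x_cm - pose.x_cm) * ux + (pose.nose_y_cm - pose.y_cm) * uy
    sign = 1.0 if forward >= 0 else -1.0
    phi = np.linspace(-np.pi / 2.0, np.pi / 2.0, 33)
    ex = sign * e.semi_major * np.cos(phi)
    ey = e.semi_minor * np.sin(phi) * sign
    xs = e.center_x + ux * ex - uy * ey
    ys = e.center_y + uy * ex + ux * ey
    return shapely.Polygon(np.column_stack([xs, ys]))


def _full_polygon(pose: FramePose, extension_cm: float):
    return shapely.Polygon(
        ellipse_boundary(social_ellipse(pose, extension_cm)))


def determine_initiator(si: SocialInteraction,
                        trajectories: dict[str, Trajectory],
                        speed_threshold: float = STATIONARY_SPEED_CM_S,
                        mutual_window: int = 6,
                        extension_cm: float = DEFAULT_EXTENSION_CM) -> str:
    """Assign the initiator of a social interaction.

    If exactly one partner is stationary (speed below ``speed_threshold``)
    at the bout onset, the other partner initiated. If both are moving, the
    animal whose front half-ellipse first overlaps the partner's social
    ellipse initiated; if both are heading toward each other and their front
    overlaps begin within ``mutual_window`` frames of each other the
    initiation is mutual. Remaining cases (both stationary, no front overlap
    found) are undetermined.
    """
    tm = trajectories[si.male_id]
    tf = trajectories[si.female_id]
    im = tm.index_of(si.start_frame)
    i_f = tf.index_of(si.start_frame)
    male_stationary = tm.speed[im] < speed_threshold
    female_stationary = tf.speed[i_f] < speed_threshold
    if male_stationary and female_stationary:
        return "undetermined"
    if female_stationary:
        return "male"
    if male_stationary:
        return "female"

    horizon = min(si.end_frame, si.start_frame + 2 * mutual_window + 1)
    f_male = f_female = None
    for frame in range(si.start_frame, horizon):
        pm = tm.pose_at(frame)
        pf = tf.pose_at(frame)
        if f_male is None and _front_half_polygon(pm, extension_cm).intersects(
                _full_polygon(pf, extension_cm)):
            f_male = frame
        if f_female is None and _front_half_polygon(pf, extension_cm).intersects(
                _full_polygon(pm, extension_cm)):
            f_female = frame
        if f_male is not None and f_female is not None:
            break
    if f_male is None and f_female is None:
        return "undetermined"
    if f_female is None:
        return "male"
    if f_male is None:
        return "female"

    pm0 = tm.pose_at(si.start_frame)
    pf0 = tf.pose_at(si.start_frame)
    toward_each_other = (
        heading_to_target_angle(pm0, pf0) < np.pi / 2.0
        and heading_to_target_angle(pf0, pm0) < np.pi / 2.0
    )
    if toward_each_other and abs(f_male - f_female) <= mutual_window:
        return "mutual"
    if f_male < f_female:
        return "male"
    if f_female < f_male:
        return "female"
    return "undetermined"


# ---------------------------------------------------------------------------
# Zone latencies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ZoneSpec:
    zone_id: int
    center_x: float
    center_y: float
    radius_cm: float = 6.0

    def __post_init__(self) -> None:
        if self.radius_cm <= 0:
            raise ValueError("zone radius must be positive")


def default_zones(arena: ArenaSpec, radius_cm: float = 6.0) -> list[ZoneSpec]:
    """Five 6 cm-radius zones: north/east/south/west central and center.

    Zone 5 sits at the arena center; zones 1-4 at the midpoints between the
    center and the wall midpoints (N, E, S, W).
    """
    w, h = arena.bounds
    return [
        ZoneSpec(1, w / 2.0, 3.0 * h / 4.0, radius_cm),
        ZoneSpec(2, 3.0 * w / 4.0, h / 2.0, radius_cm),
        ZoneSpec(3, w / 2.0, h / 4.0, radius_cm),
        ZoneSpec(4, w / 4.0, h / 2.0, radius_cm),
        ZoneSpec(5, w / 2.0, h / 2.0, radius_cm),
    ]


def _next_entry_index(inside: np.ndarray) -> np.ndarray:
    """nxt[i] = smallest j >= i with inside[j], else len(inside)."""
    n = inside.size
    idx = np.flatnonzero(inside)
    pos = np.searchsorted(idx, np.arange(n), side="left")
    nxt = np.full(n, n, dtype=np.int64)
    valid = pos < idx.size
    nxt[valid] = idx[pos[valid]]
    return nxt


def zone_latencies(trajectories: dict[str, Trajectory],
                   trigger_events: Sequence[BehaviorEvent],
                   zones: Sequence[ZoneSpec],
                   fps: float = 30.0) -> pd.DataFrame:
    """Latency for each male to first reach each zone after aggression ends.

    For every aggressive trigger and zone, the latency (s) runs from the
    event's end frame until the male's centroid first enters the zone disk
    (0 if already inside). Events where the zone is never reached before the
    recording ends are excluded from the median but counted.

    Returns a tidy frame with one row per (zone, role, mouse): columns
    ``zone_id, role, mouse_id, median_latency_s, n_events, n_unreached``.
    """
    triggers = [e for e in trigger_events if e.is_aggressive]
    male_ids = sorted({e.aggressor_id for e in triggers}
                      | {e.aggressed_id for e in triggers})
    entry: dict[tuple[str, int], np.ndarray] = {}
    for mid in male_ids:
        t = trajectories[mid]
        for z in zones:
            inside = np.hypot(t.x - z.center_x, t.y - z.center_y) <= z.radius_cm
            entry[(mid, z.zone_id)] = _next_entry_index(inside)

    rows = []
    latencies: dict[tuple[int, str, str], list[float]] = {}
    unreached: dict[tuple[int, str, str], int] = {}
    for ev in triggers:
        for role, mid in (("aggressor", ev.aggressor_id),
                          ("aggressed", ev.aggressed_id)):
            t = trajectories[mid]
            i_end = min(ev.end_frame - t.start_frame, len(t) - 1)
            for z in zones:
                nxt = entry[(mid, z.zone_id)]
                j = nxt[i_end]
                key = (z.zone_id, role, mid)
                if j >= len(t):
                    unreached[key] = unreached.get(key, 0) + 1
                else:
                    latencies.setdefault(key, []).append((j - i_end) / fps)
    keys = sorted(set(latencies) | set(unreached))
    for key in keys:
        vals = latencies.get(key, [])
        zone_id, role, mid = key
        rows.append({
            "zone_id": zone_id, "role": role, "mouse_id": mid,
            "median_latency_s": float(np.median(vals)) if vals else np.nan,
            "n_events": len(vals),
            "n_unreached": unreached.get(key, 0),
        })
    return pd.DataFrame(rows, columns=[
        "zone_id", "role", "mouse_id", "median_latency_s", "n_events",
        "n_unreached",
    ])
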
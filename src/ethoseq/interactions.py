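"""Social-ellipse construction and opposite-sex interaction detection.

A *social ellipse* is the fitted body ellipse lengthened 3 cm along the
major axis in front of and behind the animal (semi-minor axis unchanged).
Two mice are socially interacting while their social ellipses overlap; runs
of at least 6 consecutive overlapping frames (0.2 s at 30 frames/s) form a
social-interaction (SI) bout.

Overlap is decided on 64-vertex polygonal approximations of the ellipses;
the polygon intersection itself (which also covers containment) is delegated
to shapely.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import shapely

from .types import FramePose, RecordingBundle, SocialInteraction, Trajectory

__all__ = [
    "SocialEllipse",
    "social_ellipse",
    "ellipse_boundary",
    "ellipses_overlap",
    "detect_interactions",
]

DEFAULT_EXTENSION_CM = 3.0
DEFAULT_MIN_FRAMES = 6
DEFAULT_VERTICES = 64


@dataclass(frozen=True)
class SocialEllipse:
    """An ellipse in arena coordinates (center cm, orientation rad)."""

    center_x: float
    center_y: float
    orientation: float
    semi_major: float
    semi_minor: float

    def __post_init__(self) -> None:
        if self.semi_major <= 0 or self.semi_minor <= 0:
            raise ValueError("degenerate (zero-area) ellipse")


def social_ellipse(pose: FramePose,
                   extension_cm: float = DEFAULT_EXTENSION_CM) -> SocialEllipse:
    """Extend the body ellipse ``extension_cm`` in front of and behind the
    animal: same center and heading, semi-major lengthened, semi-minor kept.
    """
    if extension_cm < 0:
        raise ValueError("extension_cm must be non-negative")
    return SocialEllipse(
        center_x=pose.x_cm, center_y=pose.y_cm, orientation=pose.theta_rad,
        semi_major=pose.a_cm + extension_cm, semi_minor=pose.b_cm,
    )


def ellipse_boundary(e: SocialEllipse, n_vertices: int = DEFAULT_VERTICES
                     ) -> np.ndarray:
    """(n, 2) boundary polygon vertices of the ellipse."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    ca, sa = np.cos(e.orientation), np.sin(e.orientation)
    ex = e.semi_major * np.cos(phi)
    ey = e.semi_minor * np.sin(phi)
    return np.column_stack([
        e.center_x + ca * ex - sa * ey,
        e.center_y + sa * ex + ca * ey,
    ])


def ellipses_overlap(e1: SocialEllipse, e2: SocialEllipse,
                     n_vertices: int = DEFAULT_VERTICES) -> bool:
    """True iff the two closed elliptical regions intersect.

    Boundary contact counts as overlap. Decided on ``n_vertices``-gon
    approximations via convex-polygon intersection (intersects() also covers
    one region containing the other).
    """
    d = np.hypot(e1.center_x - e2.center_x, e1.center_y - e2.center_y)
    if d > e1.semi_major + e2.semi_major:
        return False
    if d <= e1.semi_minor + e2.semi_minor:
        return True
    p1 = shapely.Polygon(ellipse_boundary(e1, n_vertices))
    p2 = shapely.Polygon(ellipse_boundary(e2, n_vertices))
    return bool(p1.intersects(p2))


def _polygons_for_frames(t: Trajectory, idx: np.ndarray, extension_cm: float,
                         n_vertices: int) -> np.ndarray:
    """Vectorized construction of social-ellipse polygons at frame indices."""
    phi = np.linspace(0.0, 2.0 * np.pi, n_vertices, endpoint=False)
    a = (t.a[idx] + extension_cm)[:, None]
    b = t.b[idx][:, None]
    ca = np.cos(t.theta[idx])[:, None]
    sa = np.sin(t.theta[idx])[:, None]
    ex = a * np.cos(phi)[None, :]
    ey = b * np.sin(phi)[None, :]
    xs = t.x[idx][:, None] + ca * ex - sa * ey
    ys = t.y[idx][:, None] + sa * ex + ca * ey
    coords = np.stack([xs, ys], axis=-1)
    return shapely.polygons(coords)


def pair_overlap_mask(t1: Trajectory, t2: Trajectory,
                      extension_cm: float = DEFAULT_EXTENSION_CM,
                      n_vertices: int = DEFAULT_VERTICES) -> np.ndarray:
    """Per-frame boolean mask of social-ellipse overlap for one pair.

    Cheap separation/containment bounds decide most frames; only frames in
    the ambiguous annulus go through the polygon test.
    """
    if len(t1) != len(t2):
        raise ValueError("trajectories must be co-recorded (equal length)")
    d = np.hypot(t1.x - t2.x, t1.y - t2.y)
    reach = (t1.a + extension_cm) + (t2.a + extension_cm)
    sure = d <= (t1.b + t2.b)
    maybe = (d <= reach) & ~sure
    overlap = sure.copy()
    idx = np.nonzero(maybe)[0]
    if idx.size:
        p1 = _polygons_for_frames(t1, idx, extension_cm, n_vertices)
        p2 = _polygons_for_frames(t2, idx, extension_cm, n_vertices)
        overlap[idx] = shapely.intersects(p1, p2)
    return overlap


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as half-open (start, end) index pairs."""
    if not mask.any():
        return []
    padded = np.concatenate([[False], mask, [False]])
    edges = np.diff(padded.astype(np.int8))
    starts = np.nonzero(edges == 1)[0]
    ends = np.nonzero(edges == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def detect_interactions(bundle: RecordingBundle,
                        pair_filter: str = "opposite_sex",
                        min_frames: int = DEFAULT_MIN_FRAMES,
                        extension_cm: float = DEFAULT_EXTENSION_CM,
                        n_vertices: int = DEFAULT_VERTICES,
                        method: str = "ellipse",
                        centroid_threshold_cm: float = 6.0,
                        ) -> list[SocialInteraction]:
    """Detect social-interaction bouts in a recording.

    For every eligible pair, maximal runs of consecutive frames with
    overlapping social ellipses are kept if they span at least ``min_frames``
    frames; no gap merging is performed. ``method="centroid"`` switches to
    the simpler centroid-distance rule (separation <= one body length,
    6 cm by default) for sensitivity analyses.
    """
    if pair_filter not in ("opposite_sex", "all"):
        raise ValueError(f"unknown pair_filter {pair_filter!r}")
    for m in bundle.mice:
        if m.mouse_id not in bundle.trajectories:
            raise ValueError(f"missing trajectory for mouse {m.mouse_id}")

    males = bundle.males()
    females = bundle.females()
    if pair_filter == "opposite_sex":
        pairs = [(m, f) for m in males for f in females]
    else:
        ids = sorted(bundle.trajectories)
        pairs = [(a, b) for i, a in enumerate(ids) for b in ids[i + 1:]]

    out: list[SocialInteraction] = []
    for id1, id2 in pairs:
        t1, t2 = bundle.trajectories[id1], bundle.trajectories[id2]
        if method == "ellipse":
            mask = pair_overlap_mask(t1, t2, extension_cm, n_vertices)
        elif method == "centroid":
            mask = np.hypot(t1.x - t2.x, t1.y - t2.y) <= centroid_threshold_cm
        else:
            raise ValueError(f"unknown detection method {method!r}")
        offset = t1.start_frame
        for s, e in _runs(mask):
            if e - s >= min_frames:
                out.append(SocialInteraction(
                    male_id=id1, female_id=id2,
                    start_frame=s + offset, end_frame=e + offset,
                    fps=bundle.arena.fps,
                ))
    out.sort(key=lambda si: (si.start_frame, si.male_id, si.female_id))
    return out
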
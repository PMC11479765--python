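"""Shared fixtures: hand-built trajectories/recordings and small cached
synthetic cohorts used across test modules."""

import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from ethoseq.simulate import SyntheticConfig, generate_cohort
from ethoseq.types import (
    ArenaSpec,
    MouseInfo,
    RecordingBundle,
    SocialInteraction,
    Trajectory,
)

settings.register_profile(
    "ci", deadline=None, derandomize=True,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("ci")


def make_trajectory(mouse_id, x, y, theta=None, a=3.0, b=1.5, fps=30.0,
                    start_frame=0):
    """Trajectory from coordinate arrays; nose placed at the ellipse tip."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if theta is None:
        theta = np.zeros(n)
    theta = np.asarray(theta, dtype=float)
    return Trajectory(
        mouse_id, np.arange(start_frame, start_frame + n), x, y, theta,
        np.full(n, a), np.full(n, b),
        x + a * np.cos(theta), y + a * np.sin(theta), fps=fps)


def make_bundle(trajectories, events=(), arena=None, sexes=None):
    arena = arena or ArenaSpec()
    if sexes is None:
        sexes = {mid: ("M" if mid.startswith("M") else "F")
                 for mid in trajectories}
    mice = [MouseInfo(mid, sexes[mid]) for mid in sorted(trajectories)]
    return RecordingBundle(arena=arena, mice=mice,
                           trajectories=dict(trajectories),
                           events=list(events))


def episodes_to_sis(gt, fps=30.0):
    """Ground-truth planted episodes as SocialInteraction records."""
    return [SocialInteraction(e.male_id, e.female_id, e.start_frame,
                              e.end_frame, fps=fps)
            for e in gt.episodes if e.realized]


@pytest.fixture(scope="session")
def effect_cohort_schedule():
    """Strong-effect schedule-only cohort (5 x 5 h): p_approach 0.8 / 0.2."""
    cfg = SyntheticConfig(p_approach_aggressed=0.8, p_approach_aggressor=0.2)
    return generate_cohort(cfg, 5, seed=101, with_poses=False)


@pytest.fixture(scope="session")
def small_pose_recording():
    """One 10-minute full-pose recording with a guaranteed-strong effect."""
    cfg = SyntheticConfig(n_frames=10 * 60 * 30, seed=7,
                          p_approach_aggressed=0.9, p_approach_aggressor=0.3,
                          min_trigger_gap_s=20.0)
    from ethoseq.simulate import generate_recording

    return generate_recording(cfg)
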
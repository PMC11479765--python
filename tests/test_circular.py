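"""Angles, circular summaries, the Watson U2 permutation test, initiator
assignment and zone latencies."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethoseq.circular import (
    circular_summary,
    default_zones,
    determine_initiator,
    heading_to_target_angle,
    orientation_difference,
    watson_u2,
    zone_latencies,
)
from ethoseq.types import ArenaSpec, BehaviorEvent, FramePose, SocialInteraction

from conftest import make_bundle, make_trajectory


def _pose(x, y, theta, mid="M1", a=3.0, b=1.5):
    return FramePose(mid, 0, x, y, theta, a, b,
                     x + a * np.cos(theta), y + a * np.sin(theta))


# ---------------------------------------------------------------------------
# angle formula (bit-exact worked cases)
# ---------------------------------------------------------------------------

def test_heading_angle_worked_cases():
    male = _pose(0.0, 0.0, 0.0)          # heading +x
    assert heading_to_target_angle(male, _pose(0.0, 5.0, 0.0, "F1")) \
        == np.pi / 2
    assert heading_to_target_angle(male, _pose(5.0, 0.0, 0.0, "F1")) == 0.0
    assert heading_to_target_angle(male, _pose(-5.0, 0.0, 0.0, "F1")) == np.pi


def test_heading_angle_zero_vector_errors():
    male = FramePose("M1", 0, 1.0, 1.0, 0.0, 3.0, 1.5, 1.0, 1.0)  # nose=center
    with pytest.raises(ValueError):
        heading_to_target_angle(male, _pose(5.0, 0.0, 0.0, "F1"))
    with pytest.raises(ValueError):
        heading_to_target_angle(_pose(2.0, 2.0, 0.0), _pose(2.0, 2.0, 1.0))


@given(rot=st.floats(-np.pi, np.pi), dx=st.floats(-30, 30),
       dy=st.floats(-30, 30))
def test_heading_angle_rigid_motion_invariant(rot, dx, dy):
    mx, my, th = 10.0, 12.0, 0.7
    fx, fy = 20.0, 5.0
    base = heading_to_target_angle(_pose(mx, my, th), _pose(fx, fy, 0, "F1"))
    c, s = np.cos(rot), np.sin(rot)

    def rt(x, y):
        return c * x - s * y + dx, s * x + c * y + dy

    m2 = _pose(*rt(mx, my), th + rot)
    f2 = _pose(*rt(fx, fy), rot, "F1")
    assert heading_to_target_angle(m2, f2) == pytest.approx(base, abs=1e-9)
    assert 0.0 <= base <= np.pi


def test_orientation_difference_wrap():
    assert orientation_difference(_pose(0, 0, 0.1), _pose(0, 0, -0.1, "F1")) \
        == pytest.approx(0.2)
    d = orientation_difference(_pose(0, 0, np.pi - 0.05),
                               _pose(0, 0, -np.pi + 0.05, "F1"))
    assert d == pytest.approx(-0.1)
    assert orientation_difference(_pose(0, 0, 1.3), _pose(0, 0, 1.3, "F1")) \
        == 0.0


# ---------------------------------------------------------------------------
# circular summary
# ---------------------------------------------------------------------------

def test_circular_summary_cases():
    s = circular_summary(np.full(7, 1.0))
    assert s.circular_median == pytest.approx(1.0)
    assert s.circular_variance == pytest.approx(0.0, abs=1e-12)
    s = circular_summary([0, np.pi / 2, np.pi, 3 * np.pi / 2])
    assert s.circular_variance == pytest.approx(1.0, abs=1e-12)
    # brute-force arc-distance minimization over {0, 0, pi/2} picks 0
    s = circular_summary([0.0, 0.0, np.pi / 2])
    assert s.circular_median == 0.0
    with pytest.raises(ValueError):
        circular_summary([])


@given(st.lists(st.floats(0.3, 2.8), min_size=3, max_size=25))
def test_circular_median_matches_linear_median_on_small_arc(values):
    # for samples confined to an arc < pi the circular median must be one
    # of the sample values closest to the ordinary median
    s = circular_summary(values)
    arr = np.sort(np.asarray(values))
    lin = np.median(arr)
    best = arr[np.argmin(np.abs(arr - lin))]
    cost = lambda m: np.mean(np.minimum(  # noqa: E731
        np.abs(arr - m), 2 * np.pi - np.abs(arr - m)))
    assert cost(s.circular_median) <= cost(best) + 1e-12


# ---------------------------------------------------------------------------
# Watson U2
# ---------------------------------------------------------------------------

def test_watson_u2_null_identical_samples():
    rng = np.random.default_rng(1)
    x = rng.vonmises(1.0, 2.0, 60)
    res = watson_u2(x, rng.permutation(x), seed=0)
    assert res.p_value > 0.05


def test_watson_u2_detects_pi_offset():
    rng = np.random.default_rng(2)
    x = rng.vonmises(0.5, 2.0, 50)
    res = watson_u2(x, x + np.pi, n_permutations=999, seed=0)
    assert res.p_value <= 0.01
    assert res.u2_statistic > 0


def test_watson_u2_rotation_invariant_statistic():
    rng = np.random.default_rng(3)
    x = rng.vonmises(0.0, 1.0, 40)
    y = rng.vonmises(1.0, 1.0, 35)
    base = watson_u2(x, y, n_permutations=9, seed=0).u2_statistic
    for rot in (0.5, 2.0, -1.3):
        r = watson_u2(x + rot, y + rot, n_permutations=9, seed=0).u2_statistic
        assert r == pytest.approx(base, abs=1e-10)


def test_watson_u2_small_samples_error():
    with pytest.raises(ValueError):
        watson_u2([0.1, 0.2], [0.3, 0.4, 0.5, 0.6, 0.7])


def test_watson_u2_type_i_error_controlled():
    """Permutation p-values reject at close to the nominal 5% under the null."""
    rng = np.random.default_rng(4)
    rejections = 0
    n_rep = 500
    for _ in range(n_rep):
        pooled = rng.vonmises(0.0, 1.5, 40)
        res = watson_u2(pooled[:20], pooled[20:], n_permutations=199,
                        seed=int(rng.integers(2**31)))
        rejections += res.p_value <= 0.05
    assert rejections / n_rep <= 0.07


# ---------------------------------------------------------------------------
# initiator assignment
# ---------------------------------------------------------------------------

def _initiator_setup(male_moving=True, female_moving=False):
    """Male approaches a (possibly stationary) female from the left."""
    n = 60
    mx = np.linspace(0, 29.5, n)     # moving right toward the female
    fx = np.full(n, 35.0)
    fy = np.full(n, 0.0)
    if female_moving:
        fy = np.linspace(0, 2.0, n)  # drifts upward, clearly above threshold
    if not male_moving:
        mx = np.full(n, 30.0)
    trajs = {
        "M1": make_trajectory("M1", mx, np.zeros(n), np.zeros(n)),
        "F1": make_trajectory("F1", fx, fy, np.full(n, np.pi / 2)),
    }
    si = SocialInteraction("M1", "F1", 55, 60)
    return si, trajs


def test_initiator_stationary_partner_rule():
    si, trajs = _initiator_setup(male_moving=True, female_moving=False)
    assert determine_initiator(si, trajs) == "male"
    si, trajs = _initiator_setup(male_moving=False, female_moving=True)
    assert determine_initiator(si, trajs) == "female"


def test_initiator_both_stationary_undetermined():
    si, trajs = _initiator_setup(male_moving=False, female_moving=False)
    assert determine_initiator(si, trajs) == "undetermined"


def test_initiator_swap_antisymmetric():
    si, trajs = _initiator_setup(male_moving=True, female_moving=False)
    swapped = {"M1": make_trajectory("M1", trajs["F1"].x, trajs["F1"].y,
                                     trajs["F1"].theta),
               "F1": make_trajectory("F1", trajs["M1"].x, trajs["M1"].y,
                                     trajs["M1"].theta)}
    assert determine_initiator(si, swapped) == "female"


def test_initiator_matches_planted_on_synthetic(small_pose_recording):
    """Planted approaches are male-initiated; the assigned initiator should
    agree for at least 95% of detected bouts (pooled over recordings)."""
    from ethoseq.interactions import detect_interactions
    from ethoseq.simulate import SyntheticConfig, generate_recording

    calls = []
    bundle, _ = small_pose_recording
    sis = detect_interactions(bundle)
    assert sis, "expected planted interactions"
    calls += [determine_initiator(si, bundle.trajectories) for si in sis]
    for seed in (8, 9):
        cfg = SyntheticConfig(n_frames=10 * 60 * 30, seed=seed,
                              p_approach_aggressed=0.9,
                              p_approach_aggressor=0.3,
                              min_trigger_gap_s=20.0)
        b, _ = generate_recording(cfg)
        calls += [determine_initiator(si, b.trajectories)
                  for si in detect_interactions(b)]
    assert len(calls) >= 30
    assert np.mean([c == "male" for c in calls]) >= 0.95


# ---------------------------------------------------------------------------
# zone latencies
# ---------------------------------------------------------------------------

def test_default_zone_layout():
    zones = default_zones(ArenaSpec())
    assert [z.zone_id for z in zones] == [1, 2, 3, 4, 5]
    assert (zones[4].center_x, zones[4].center_y) == (38.1, 38.1)
    assert zones[0].center_y > zones[2].center_y  # north above south


def test_zone_latency_already_inside_and_straight_run():
    n = 200
    arena = ArenaSpec()
    zones = default_zones(arena)
    # M1 sits at the center zone; M2 runs toward it at 10 cm/s from 30 cm
    # outside the zone boundary (36 cm from the center, radius 6)
    m1 = make_trajectory("M1", np.full(n, 38.1), np.full(n, 38.1))
    x2 = np.minimum(38.1 - 36.0 + 10.0 * np.arange(n) / 30.0, 38.1)
    m2 = make_trajectory("M2", x2, np.full(n, 38.1))
    ev = BehaviorEvent("chase", "M1", "M2", 0, 2)
    df = zone_latencies({"M1": m1, "M2": m2}, [ev], zones, fps=30.0)
    center = df[(df.zone_id == 5)]
    agg = center[center.role == "aggressor"].iloc[0]
    assert agg.median_latency_s == pytest.approx(0.0)
    ged = center[center.role == "aggressed"].iloc[0]
    # 30 cm to cover at 10 cm/s, starting at the event end (frame 2)
    assert ged.median_latency_s == pytest.approx(3.0, abs=0.1)


def test_zone_latency_unreached_counted():
    n = 50
    m1 = make_trajectory("M1", np.full(n, 1.0), np.full(n, 1.0))
    m2 = make_trajectory("M2", np.full(n, 2.0), np.full(n, 1.0))
    ev = BehaviorEvent("chase", "M1", "M2", 0, 2)
    df = zone_latencies({"M1": m1, "M2": m2}, [ev],
                        default_zones(ArenaSpec()), fps=30.0)
    assert (df.n_unreached == 1).all()
    assert df.median_latency_s.isna().all()
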
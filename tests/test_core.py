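"""Domain types, table I/O, per-frame kinematics, aggression summaries and
the post-hoc event refinement filters."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethoseq.io import (
    FormatError,
    read_event_table,
    read_pose_table,
    write_event_table,
    write_pose_table,
)
from ethoseq.kinematics import (
    aggression_summary,
    compute_speed,
    exploration_fraction,
    refine_events,
)
from ethoseq.types import ArenaSpec, BehaviorEvent, MouseInfo

from conftest import make_bundle, make_trajectory


# ---------------------------------------------------------------------------
# events and roles
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("label,actor,recipient,aggressor,aggressed", [
    ("chase", "M1", "M2", "M1", "M2"),
    ("flee", "M2", "M1", "M1", "M2"),
])
def test_role_derivation(label, actor, recipient, aggressor, aggressed):
    ev = BehaviorEvent(label, actor, recipient, 10, 40, confidence=1.2)
    assert ev.aggressor_id == aggressor
    assert ev.aggressed_id == aggressed


def test_walk_event_has_no_roles():
    ev = BehaviorEvent("walk", "M1", None, 5, 30, confidence=2.0)
    assert ev.aggressor_id is None and ev.aggressed_id is None


@pytest.mark.parametrize("kwargs", [
    dict(label="hop", actor_id="M1", recipient_id="M2",
         start_frame=0, end_frame=5),
    dict(label="chase", actor_id="M1", recipient_id="M2",
         start_frame=10, end_frame=10),
    dict(label="chase", actor_id="M1", recipient_id="M1",
         start_frame=0, end_frame=5),
])
def test_invalid_events_rejected(kwargs):
    with pytest.raises(ValueError):
        BehaviorEvent(**kwargs)


# ---------------------------------------------------------------------------
# table round trips
# ---------------------------------------------------------------------------

def test_pose_table_round_trip(tmp_path):
    rng = np.random.default_rng(0)
    trajs = {
        mid: make_trajectory(mid, rng.uniform(5, 70, 100),
                             rng.uniform(5, 70, 100),
                             rng.uniform(-np.pi, np.pi, 100))
        for mid in ("M1", "M2", "F1", "F2")
    }
    bundle = make_bundle(trajs)
    path = tmp_path / "poses.csv"
    write_pose_table(bundle, path)
    back = read_pose_table(path, ArenaSpec(),
                           mice=[MouseInfo(m, s) for m, s in
                                 [("M1", "M"), ("M2", "M"),
                                  ("F1", "F"), ("F2", "F")]])
    assert set(back.trajectories) == set(trajs)
    for mid, t in trajs.items():
        t2 = back.trajectories[mid]
        assert len(t2) == 100
        np.testing.assert_allclose(t2.x, t.x)
        np.testing.assert_allclose(t2.theta, t.theta)
        np.testing.assert_allclose(t2.nose_y, t.nose_y)


def test_pose_table_gap_error(tmp_path):
    t = make_trajectory("M1", np.zeros(10), np.zeros(10))
    bundle = make_bundle({"M1": t}, sexes={"M1": "M"})
    path = tmp_path / "poses.csv"
    write_pose_table(bundle, path)
    import pandas as pd

    df = pd.read_csv(path)
    df = df[df["frame"] != 10 - 5]  # punch a hole
    df.to_csv(path, index=False)
    with pytest.raises(ValueError, match="gap|contiguous"):
        read_pose_table(path, ArenaSpec())


def test_empty_pose_table_ok(tmp_path):
    path = tmp_path / "poses.csv"
    path.write_text("recording_id,mouse_id,frame,x_cm,y_cm,theta_rad,"
                    "a_cm,b_cm,nose_x_cm,nose_y_cm\n")
    bundle = read_pose_table(path, ArenaSpec())
    assert bundle.trajectories == {}


def test_missing_column_names_column(tmp_path):
    path = tmp_path / "poses.csv"
    path.write_text("recording_id,mouse_id,frame,x_cm,y_cm\n")
    with pytest.raises(FormatError, match="theta_rad"):
        read_pose_table(path, ArenaSpec())


def test_event_table_round_trip(tmp_path):
    events = [
        BehaviorEvent("chase", "M1", "M2", 10, 40, 1.2),
        BehaviorEvent("flee", "M2", "M1", 50, 80, 0.9),
        BehaviorEvent("walk", "M1", None, 5, 30, 2.0),
    ]
    path = tmp_path / "events.csv"
    write_event_table(events, path)
    back = read_event_table(path)
    assert [e.start_frame for e in back] == [5, 10, 50]  # start-sorted
    chase = next(e for e in back if e.label == "chase")
    assert chase.aggressor_id == "M1" and chase.aggressed_id == "M2"
    flee = next(e for e in back if e.label == "flee")
    assert flee.aggressor_id == "M1" and flee.aggressed_id == "M2"
    walk = next(e for e in back if e.label == "walk")
    assert walk.recipient_id is None


# ---------------------------------------------------------------------------
# speed
# ---------------------------------------------------------------------------

def test_speed_worked_cases():
    t = make_trajectory("M1", [0, 1], [0, 0])
    np.testing.assert_allclose(compute_speed(t, 30.0), [30.0, 30.0])
    t = make_trajectory("M1", [2, 2, 2], [3, 3, 3])
    np.testing.assert_allclose(compute_speed(t, 30.0), 0.0)
    t = make_trajectory("M1", [0, 3], [0, 4])
    np.testing.assert_allclose(compute_speed(t, 30.0)[1], 150.0)  # 3-4-5
    with pytest.raises(ValueError):
        compute_speed(make_trajectory("M1", [0.0], [0.0]), 30.0)


@given(dx=st.floats(-50, 50), dy=st.floats(-50, 50),
       scale=st.sampled_from([15.0, 30.0, 60.0]))
def test_speed_translation_invariant_and_fps_linear(dx, dy, scale):
    rng = np.random.default_rng(3)
    x = rng.uniform(0, 70, 50)
    y = rng.uniform(0, 70, 50)
    base = compute_speed(make_trajectory("M1", x, y), 30.0)
    shifted = compute_speed(make_trajectory("M1", x + dx, y + dy), 30.0)
    np.testing.assert_allclose(shifted, base, atol=1e-8)
    np.testing.assert_allclose(
        compute_speed(make_trajectory("M1", x, y), scale),
        base * scale / 30.0, rtol=1e-9)


# ---------------------------------------------------------------------------
# exploration
# ---------------------------------------------------------------------------

def test_exploration_single_point_81cm2():
    t = make_trajectory("M1", np.full(100, 10.0), np.full(100, 10.0))
    frac = exploration_fraction(t, ArenaSpec(), 81.0)
    # 9x9 grid of 9-cm bins covers the 76.2 cm square (edge bins partial)
    assert frac == pytest.approx(100.0 / 81.0)


def test_exploration_full_grid_and_monotonicity():
    arena = ArenaSpec()
    side = 3.0
    centers = [(i * side + side / 2, j * side + side / 2)
               for i in range(26) for j in range(26)]
    xs = np.array([c[0] for c in centers])
    ys = np.array([c[1] for c in centers])
    t = make_trajectory("M1", xs, ys)
    assert exploration_fraction(t, arena, 9.0) == pytest.approx(100.0)
    p = make_trajectory("M1", np.full(10, 40.0), np.full(10, 40.0))
    fractions = [exploration_fraction(p, arena, a) for a in (9.0, 36.0, 81.0)]
    assert fractions == sorted(fractions)  # non-decreasing in bin area


def test_exploration_bin_too_large():
    t = make_trajectory("M1", [1.0, 2.0], [1.0, 2.0])
    with pytest.raises(ValueError):
        exploration_fraction(t, ArenaSpec(), 10000.0)


# ---------------------------------------------------------------------------
# aggression summary
# ---------------------------------------------------------------------------

def _agg_events(n1, n2):
    out = []
    f = 0
    for _ in range(n1):
        out.append(BehaviorEvent("chase", "M1", "M2", f, f + 10))
        f += 20
    for _ in range(n2):
        out.append(BehaviorEvent("chase", "M2", "M1", f, f + 10))
        f += 20
    return out


@pytest.mark.parametrize("n1,n2,score", [(30, 10, 0.5), (10, 10, 0.0),
                                         (216, 0, 1.0)])
def test_aggression_score(n1, n2, score):
    s = aggression_summary(_agg_events(n1, n2), ["M1", "M2"])
    assert s.aggression_score == pytest.approx(score)
    if n1 == n2:
        assert s.chi_square_p == pytest.approx(1.0)
        assert s.more_aggressive_id is None
    elif n1 > n2:
        assert s.more_aggressive_id == "M1"


def test_aggression_score_antisymmetric():
    ev = _agg_events(25, 13)
    s12 = aggression_summary(ev, ["M1", "M2"])
    s21 = aggression_summary(ev, ["M2", "M1"])
    assert s12.aggression_score == pytest.approx(-s21.aggression_score)


def test_aggression_zero_events_flagged():
    s = aggression_summary([], ["M1", "M2"])
    assert not s.defined and s.aggression_score is None


# ---------------------------------------------------------------------------
# refinement
# ---------------------------------------------------------------------------

def _far_pair_trajs(n=200):
    """Two males 20 cm apart, a female far away; everyone drifting slowly."""
    base = np.linspace(0, 1, n)
    return {
        "M1": make_trajectory("M1", 10 + base, np.full(n, 10.0)),
        "M2": make_trajectory("M2", 30 + base, np.full(n, 10.0)),
        "F1": make_trajectory("F1", np.full(n, 70.0), np.full(n, 70.0)),
    }


def test_refine_rejects_short_chase_and_low_confidence_flee():
    trajs = _far_pair_trajs()
    events = [
        BehaviorEvent("chase", "M1", "M2", 0, 6, 0.9),     # not > 6 frames
        BehaviorEvent("flee", "M2", "M1", 20, 40, 0.6),    # conf not > 0.7
        BehaviorEvent("walk", "M1", None, 50, 75, 1.5),    # passes
    ]
    rep = refine_events(events, trajs, sexes={"M1": "M", "M2": "M",
                                              "F1": "F"})
    assert [e.label for e in rep.kept] == ["walk"]
    assert rep.rejections["chase:duration_gt_6_frames"] == 1
    assert rep.rejections["flee:confidence_gt_0.7"] == 1


def test_refine_subset_and_idempotent():
    trajs = _far_pair_trajs()
    events = [
        BehaviorEvent("walk", "M1", None, 0, 25, 1.5),
        BehaviorEvent("walk", "M1", None, 30, 45, 1.5),   # too short
        BehaviorEvent("chase", "M1", "M2", 60, 80, 0.9),  # dist 20 < 30 ok
        BehaviorEvent("fight", "M1", "M2", 100, 120, 2.0),  # too short
    ]
    rep1 = refine_events(events, trajs, sexes={"M1": "M", "M2": "M",
                                               "F1": "F"})
    assert set(id(e) for e in rep1.kept) <= set(id(e) for e in events)
    rep2 = refine_events(rep1.kept, trajs, sexes={"M1": "M", "M2": "M",
                                                  "F1": "F"})
    assert rep2.kept == rep1.kept
    assert rep2.rejections == {}


def test_refine_missing_confidence_errors():
    events = [BehaviorEvent("walk", "M1", None, 0, 30, None)]
    with pytest.raises(ValueError, match="confidence"):
        refine_events(events, _far_pair_trajs(),
                      sexes={"M1": "M", "M2": "M", "F1": "F"})
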
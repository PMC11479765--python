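"""Triggered-sequence extraction, controls, hour binning, three-step typing,
phase profiles and fight association."""

import numpy as np
import pytest

from ethoseq.sequences import (
    classify_three_step,
    control_triggers,
    extract_triggered_sequences,
    fights_following,
    hour_binned_state_proportions,
    phase_profiles,
    summarize_sequences,
)
from ethoseq.types import BehaviorEvent, SocialInteraction

from conftest import episodes_to_sis, make_trajectory


def chase(start, end, aggressor="M1", aggressed="M2"):
    return BehaviorEvent("chase", aggressor, aggressed, start, end)


def si(male, start, end, female="F1"):
    return SocialInteraction(male, female, start, end)


# ---------------------------------------------------------------------------
# extraction
# ---------------------------------------------------------------------------

def test_extraction_latency_and_duration_arithmetic():
    seqs = extract_triggered_sequences(
        [chase(100, 200)], [si("M2", 235, 280)], fps=30.0)
    assert len(seqs) == 1
    s = seqs[0]
    assert s.latency_s == pytest.approx(35 / 30)   # ~1.17 s
    assert s.duration_s == pytest.approx(1.5)
    assert s.partner_state == "aggressed"


def test_extraction_negative_latency_retained():
    seqs = extract_triggered_sequences(
        [chase(100, 200)], [si("M2", 180, 220)], fps=30.0)
    assert len(seqs) == 1
    assert seqs[0].latency_s == pytest.approx(-20 / 30)


def test_extraction_window_ends_at_next_trigger():
    triggers = [chase(0, 30), chase(300, 330)]
    sis = [si("M2", 400, 430)]  # falls only in the second trigger's window
    seqs = extract_triggered_sequences(triggers, sis)
    assert len(seqs) == 1
    assert seqs[0].trigger.start_frame == 300


def test_each_si_attributed_once_and_count_bound():
    triggers = [chase(0, 30), chase(300, 330)]
    sis = [si("M2", 40, 70), si("M1", 100, 130), si("M2", 350, 380)]
    seqs = extract_triggered_sequences(triggers, sis)
    assert len(seqs) <= len(triggers)
    used = [s.si for s in seqs]
    assert len(used) == len(set(id(u) for u in used))
    # the first trigger takes the earliest SI only
    assert seqs[0].si.start_frame == 40


def test_extraction_frame_offset_invariant():
    base = extract_triggered_sequences([chase(100, 200)],
                                       [si("M2", 235, 280)])
    off = 5000
    shifted = extract_triggered_sequences(
        [chase(100 + off, 200 + off)], [si("M2", 235 + off, 280 + off)])
    assert shifted[0].latency_s == base[0].latency_s
    assert shifted[0].duration_s == base[0].duration_s


def test_extraction_matches_planted_pairings(effect_cohort_schedule):
    for bundle, gt in effect_cohort_schedule:
        triggers = [e for e in bundle.events if e.is_aggressive]
        seqs = extract_triggered_sequences(triggers, episodes_to_sis(gt))
        got = {triggers.index(s.trigger): s.si.start_frame for s in seqs}
        expected = {ti: gt.episodes[ei].start_frame
                    for ti, ei in gt.pairings.items()}
        assert got == expected


def test_summarize_single_sequence():
    seqs = extract_triggered_sequences([chase(0, 30)], [si("M2", 40, 70)])
    df = summarize_sequences(seqs)
    assert df.loc[df.group == "aggressed", "n"].item() == 1
    assert "aggressor" not in set(df.group)


def test_effect_cohort_aggressed_counts_dominate(effect_cohort_schedule):
    for bundle, gt in effect_cohort_schedule:
        triggers = [e for e in bundle.events if e.is_aggressive]
        seqs = extract_triggered_sequences(triggers, episodes_to_sis(gt))
        states = [s.partner_state for s in seqs]
        assert states.count("aggressed") > states.count("aggressor")


# ---------------------------------------------------------------------------
# control triggers
# ---------------------------------------------------------------------------

def test_control_triggers_matching_and_determinism():
    walks = [BehaviorEvent("walk", "M1", None, i * 100, i * 100 + 30)
             for i in range(100)]
    a = control_triggers(walks, "walk", 40, seed=9)
    b = control_triggers(walks, "walk", 40, seed=9)
    assert len(a) == 40
    assert [e.start_frame for e in a] == [e.start_frame for e in b]
    few = [BehaviorEvent("investigate", "M1", "M2", i * 100, i * 100 + 30)
           for i in range(30)]
    assert len(control_triggers(few, "investigate", 40, seed=0)) == 30
    assert control_triggers([], "walk", 10, seed=0) == []


def test_walk_triggers_show_no_state_asymmetry(effect_cohort_schedule):
    """The planted effect is aggression-specific: walk-triggered sequences
    split roughly evenly between walker and non-walker partners."""
    counts = {"walker": 0, "non_walker": 0}
    for bundle, gt in effect_cohort_schedule:
        walks = [e for e in bundle.events if e.label == "walk"]
        seqs = extract_triggered_sequences(walks, episodes_to_sis(gt))
        for s in seqs:
            counts[s.partner_state] += 1
    total = sum(counts.values())
    assert total > 100
    frac = counts["walker"] / total
    assert 0.35 < frac < 0.65


# ---------------------------------------------------------------------------
# hour binning
# ---------------------------------------------------------------------------

def test_hour_bins_normalize_and_flag_sparse():
    n_frames = 5 * 3600 * 30
    seqs = extract_triggered_sequences(
        [chase(i * 1000, i * 1000 + 30) for i in range(10)],
        [si("M2" if i % 2 else "M1", i * 1000 + 40, i * 1000 + 70)
         for i in range(10)])
    df = hour_binned_state_proportions(seqs, n_frames)
    hour1 = df[df.hour_bin == 1]
    assert hour1.proportion.sum() == pytest.approx(1.0)
    assert df[df.hour_bin > 1].n.sum() == 0  # all sequences in hour 1
    assert all(s.hour_bin == 1 for s in seqs)


def test_hour_bins_late_sequence_goes_to_last_bin():
    n_frames = 100
    seqs = extract_triggered_sequences([chase(0, 10)], [si("M2", 95, 140)])
    hour_binned_state_proportions(seqs, n_frames, n_bins=5)
    assert seqs[0].hour_bin == 5


# ---------------------------------------------------------------------------
# three-step typing
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("si1_male,si2_male,f2,expected_type", [
    ("M2", "M1", "F1", 1),  # aggressed then aggressor, same female
    ("M1", "M2", "F1", 2),  # aggressor then aggressed, same female
    ("M2", "M1", "F2", 3),  # aggressed then aggressor, other female
    ("M1", "M2", "F2", 4),  # aggressor then aggressed, other female
])
def test_three_step_types_match_taxonomy(si1_male, si2_male, f2,
                                         expected_type):
    triggers = [chase(0, 30)]  # aggressor M1, aggressed M2
    sis = [si(si1_male, 40, 70, "F1"), si(si2_male, 80, 110, f2)]
    seqs = extract_triggered_sequences(triggers, sis)
    ts = classify_three_step(seqs, sis)
    assert len(ts) == 1
    assert ts[0].sequence_type == expected_type
    assert ts[0].same_female == (f2 == "F1")


def test_three_step_requires_second_si_before_next_trigger():
    triggers = [chase(0, 30), chase(200, 230)]
    sis = [si("M2", 40, 70), si("M1", 250, 280)]
    seqs = extract_triggered_sequences(triggers, sis)
    ts = classify_three_step(seqs, sis)
    # the first trigger has no second SI inside its window
    assert all(t.trigger.start_frame != 0 for t in ts)


def test_three_step_types_partition(effect_cohort_schedule):
    for bundle, gt in effect_cohort_schedule:
        triggers = [e for e in bundle.events if e.is_aggressive]
        sis = episodes_to_sis(gt)
        seqs = extract_triggered_sequences(triggers, sis)
        ts = classify_three_step(seqs, sis)
        assert ts
        assert all(t.sequence_type in (1, 2, 3, 4) for t in ts)


def test_three_step_matches_planted_types(effect_cohort_schedule):
    for bundle, gt in effect_cohort_schedule:
        triggers = [e for e in bundle.events if e.is_aggressive]
        sis = episodes_to_sis(gt)
        seqs = extract_triggered_sequences(triggers, sis)
        ts = classify_three_step(seqs, sis)
        got = {triggers.index(t.trigger): t.sequence_type for t in ts}
        assert got == gt.sequence_types


# ---------------------------------------------------------------------------
# phase profiles
# ---------------------------------------------------------------------------

def _static_three_step(dist=10.0, n=1200):
    """All mice frozen: male-female distances constant at ``dist``."""
    trajs = {
        "M1": make_trajectory("M1", np.full(n, 20.0), np.full(n, 20.0)),
        "M2": make_trajectory("M2", np.full(n, 20.0), np.full(n, 30.0)),
        "F1": make_trajectory("F1", np.full(n, 20.0 + dist),
                              np.full(n, 20.0)),
        "F2": make_trajectory("F2", np.full(n, 60.0), np.full(n, 60.0)),
    }
    triggers = [chase(100, 160)]
    sis = [si("M2", 200, 260, "F1"), si("M1", 300, 360, "F1")]
    seqs = extract_triggered_sequences(triggers, sis)
    ts = classify_three_step(seqs, sis)
    return ts, trajs


def test_phase_profile_flat_for_constant_separation():
    ts, trajs = _static_three_step(dist=10.0)
    prof = phase_profiles(ts, trajs)
    agg_f = prof.profiles["aggressor_female"]
    for phase in ("agg", "gap", "si", "post"):
        assert np.allclose(agg_f[phase], 10.0)
    pts = prof.points
    assert np.allclose(
        pts[pts.dyad == "aggressor_female"].distance_cm, 10.0)


def test_phase_interpolation_preserves_endpoints():
    n = 1200
    # female walks away during the SI: distance ramps 10 -> 20
    fx = np.full(n, 30.0)
    fx[200:260] = 30.0 + np.linspace(0, 10, 60)
    fx[260:] = 40.0
    trajs = {
        "M1": make_trajectory("M1", np.full(n, 20.0), np.full(n, 20.0)),
        "M2": make_trajectory("M2", np.full(n, 20.0), np.full(n, 40.0)),
        "F1": make_trajectory("F1", fx, np.full(n, 20.0)),
        "F2": make_trajectory("F2", np.full(n, 70.0), np.full(n, 70.0)),
    }
    triggers = [chase(100, 160)]
    sis = [si("M2", 200, 260, "F1"), si("M1", 300, 360, "F1")]
    seqs = extract_triggered_sequences(triggers, sis)
    ts = classify_three_step(seqs, sis)
    prof = phase_profiles(ts, trajs)
    series = prof.profiles["aggressor_female"]["si"][0]
    assert series[0] == pytest.approx(10.0)
    assert series[-1] == pytest.approx(np.hypot(fx[259] - 20.0, 0.0))


def test_phase_profile_zero_length_gap_skipped():
    n = 1200
    trajs = _static_three_step()[1]
    triggers = [chase(100, 200)]
    sis = [si("M2", 150, 260, "F1"), si("M1", 300, 360, "F1")]  # SI in trigger
    seqs = extract_triggered_sequences(triggers, sis)
    ts = classify_three_step(seqs, sis)
    prof = phase_profiles(ts, trajs)
    gap = prof.profiles["aggressed_female"]["gap"]
    assert gap.shape[1] == 0 or np.isnan(gap).all()


# ---------------------------------------------------------------------------
# fight association
# ---------------------------------------------------------------------------

def test_fights_following_counts():
    ts, _ = _static_three_step()
    assert ts[0].sequence_type == 1
    no_fights = fights_following(ts, [])
    assert (no_fights.pct_with_fight.fillna(0) == 0).all()
    fight = BehaviorEvent("fight", "M1", "M2", 400, 460)
    with_fight = fights_following(ts, [fight])
    t1 = with_fight[with_fight.group == "type1"].iloc[0]
    assert t1.pct_with_fight == pytest.approx(100.0)
    assert ts[0].fight_followed


def test_fights_following_window_cap():
    ts, _ = _static_three_step()
    late_fight = BehaviorEvent("fight", "M1", "M2", 2000, 2060)
    # unlimited window (no later trigger): attributed
    assert fights_following(ts, [late_fight]).n_with_fight.sum() == 1
    # 5-second horizon after the second SI: not attributed
    capped = fights_following(ts, [late_fight], fps=30.0, window_s=5.0)
    assert capped.n_with_fight.sum() == 0


def test_fight_rate_lower_after_type1_when_planted(effect_cohort_schedule):
    """With the default planted fight probabilities, type-1 sequences are
    followed by fights less often than types 2-4 pooled."""
    n1 = nf1 = no = nfo = 0
    for bundle, gt in effect_cohort_schedule:
        triggers = [e for e in bundle.events if e.is_aggressive]
        sis = episodes_to_sis(gt)
        seqs = extract_triggered_sequences(triggers, sis)
        ts = classify_three_step(seqs, sis)
        fights = [e for e in bundle.events if e.label == "fight"]
        df = fights_following(ts, fights)
        row1 = df[df.group == "type1"].iloc[0]
        rowo = df[df.group == "other"].iloc[0]
        n1 += row1.n_sequences
        nf1 += row1.n_with_fight
        no += rowo.n_sequences
        nfo += rowo.n_with_fight
    assert n1 > 50 and no > 20
    assert nf1 / n1 < nfo / no
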
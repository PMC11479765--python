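"""Triggered-sequence extraction and downstream sequence analyses.

An *aggression-triggered sequence* pairs an aggressive male-male bout with
the first male-female social interaction (SI) that starts at or after the
bout's onset and before the next trigger. The SI partner's behavioral state
(aggressor vs aggressed; walker vs non-walker and investigator vs
investigated for the control triggers) is the central grouping variable.

Three-step sequences add the next SI after the first one and classify the
triple into four types keyed on which male the second SI involves and
whether it is the same female:

====  ====================  =============================
type  first SI              second SI
====  ====================  =============================
1     aggressed + female    aggressor + same female
2     aggressor + female    aggressed + same female
3     aggressed + female    aggressor + other female
4     aggressor + female    aggressed + other female
====  ====================  =============================

Type 1 is the bait-and-switch signature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .types import BehaviorEvent, SocialInteraction, Trajectory

__all__ = [
    "TriggeredSequence",
    "extract_triggered_sequences",
    "summarize_sequences",
    "control_triggers",
    "hour_binned_state_proportions",
    "ThreeStepSequence",
    "classify_three_step",
    "PhaseProfileSet",
    "phase_profiles",
    "fights_following",
]

#: partner-state labels by trigger label: (state if SI male is the
#: actor-derived "active" role, state otherwise)
_STATE_LABELS = {
    "chase": ("aggressor", "aggressed"),
    "flee": ("aggressor", "aggressed"),
    "walk": ("walker", "non_walker"),
    "investigate": ("investigator", "investigated"),
}


@dataclass
class TriggeredSequence:
    """One (trigger event -> first following SI) pair."""

    trigger: BehaviorEvent
    si: SocialInteraction
    latency_s: float
    duration_s: float
    partner_male_id: str
    partner_state: str
    hour_bin: Optional[int] = None


def _partner_state(trigger: BehaviorEvent, male_id: str) -> Optional[str]:
    if trigger.is_aggressive:
        if male_id == trigger.aggressor_id:
            return "aggressor"
        if male_id == trigger.aggressed_id:
            return "aggressed"
        return None
    if trigger.label == "walk":
        return "walker" if male_id == trigger.actor_id else "non_walker"
    if trigger.label == "investigate":
        if male_id == trigger.actor_id:
            return "investigator"
        if male_id == trigger.recipient_id:
            return "investigated"
        return None
    return None


def extract_triggered_sequences(
        triggers: Sequence[BehaviorEvent],
        interactions: Sequence[SocialInteraction],
        fps: float = 30.0,
        attribution: str = "first_after_onset",
        latency_cap_s: Optional[float] = None,
) -> list[TriggeredSequence]:
    """Pair each trigger with the first SI starting in its window.

    A trigger's window runs from its own start frame to the next trigger's
    start frame (unbounded for the last trigger). The earliest SI in the
    window forms the sequence; the latency ``(si.start - trigger.end)/fps``
    may be negative when the SI begins while the trigger is still running.
    Each SI is attributed to at most one trigger (its nearest preceding
    one). Triggers whose window holds no SI yield no sequence.

    ``latency_cap_s`` optionally discards sequences whose latency exceeds
    the cap (no cap by default).
    """
    if attribution != "first_after_onset":
        raise ValueError(f"unknown attribution rule {attribution!r}")
    trig = sorted(triggers, key=lambda e: (e.start_frame, e.end_frame))
    sis = sorted(interactions, key=lambda s: s.start_frame)
    out: list[TriggeredSequence] = []
    si_i = 0
    for i, t in enumerate(trig):
        window_end = trig[i + 1].start_frame if i + 1 < len(trig) else np.inf
        # skip SIs before this trigger's onset (they belonged to earlier
        # windows or precede all triggers)
        while si_i < len(sis) and sis[si_i].start_frame < t.start_frame:
            si_i += 1
        if si_i >= len(sis) or sis[si_i].start_frame >= window_end:
            continue
        si = sis[si_i]
        si_i += 1
        state = _partner_state(t, si.male_id)
        if state is None:
            continue
        latency = (si.start_frame - t.end_frame) / fps
        if latency_cap_s is not None and latency > latency_cap_s:
            continue
        out.append(TriggeredSequence(
            trigger=t, si=si, latency_s=latency,
            duration_s=(si.end_frame - si.start_frame) / fps,
            partner_male_id=si.male_id, partner_state=state,
        ))
    return out


def summarize_sequences(sequences: Sequence[TriggeredSequence],
                        group_by: str = "partner_state") -> pd.DataFrame:
    """Counts and median latency/duration per partner state (or male).

    Returns one row per group with columns ``group, n, median_latency_s,
    median_duration_s``.
    """
    if not sequences:
        raise ValueError("no sequences to summarize")
    if group_by == "partner_state":
        key = lambda s: s.partner_state  # noqa: E731
    elif group_by == "partner_male_id":
        key = lambda s: s.partner_male_id  # noqa: E731
    else:
        raise ValueError(f"unknown group_by {group_by!r}")
    rows = []
    groups: dict[str, list[TriggeredSequence]] = {}
    for s in sequences:
        groups.setdefault(key(s), []).append(s)
    for g in sorted(groups):
        seqs = groups[g]
        rows.append({
            "group": g,
            "n": len(seqs),
            "median_latency_s": float(np.median([s.latency_s for s in seqs])),
            "median_duration_s": float(np.median([s.duration_s for s in seqs])),
        })
    return pd.DataFrame(rows)


def control_triggers(events: Sequence[BehaviorEvent], kind: str,
                     n_match: int, seed: Optional[int] = None
                     ) -> list[BehaviorEvent]:
    """Sample-size-matched control triggers (walks or investigations).

    Draws a random subset of size ``n_match`` without replacement; if fewer
    candidate events exist, all are used. Reproducible for a fixed seed.
    """
    if kind not in ("walk", "investigate"):
        raise ValueError("control trigger kind must be 'walk' or 'investigate'")
    candidates = [e for e in events if e.label == kind]
    if not candidates:
        return []
    if len(candidates) <= n_match:
        return sorted(candidates, key=lambda e: e.start_frame)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n_match, replace=False)
    return sorted((candidates[i] for i in idx), key=lambda e: e.start_frame)


def hour_binned_state_proportions(sequences: Sequence[TriggeredSequence],
                                  recording_frames: int,
                                  fps: float = 30.0,
                                  n_bins: int = 5) -> pd.DataFrame:
    """Per-hour-bin proportion of sequences in each partner state.

    Sequences are binned by the SI's start time into ``n_bins`` equal bins
    spanning the recording; anything past the final bin is assigned to it.
    Also fills each sequence's ``hour_bin`` field (1-based). Proportions
    within a bin sum to 1 over the states present.
    """
    if recording_frames <= 0:
        raise ValueError("recording_frames must be positive")
    bin_frames = recording_frames / n_bins
    counts: dict[tuple[int, str], int] = {}
    for s in sequences:
        b = min(int(s.si.start_frame // bin_frames), n_bins - 1) + 1
        s.hour_bin = b
        counts[(b, s.partner_state)] = counts.get((b, s.partner_state), 0) + 1
    rows = []
    states = sorted({st for _, st in counts})
    for b in range(1, n_bins + 1):
        total = sum(counts.get((b, st), 0) for st in states)
        for st in states:
            n = counts.get((b, st), 0)
            rows.append({
                "hour_bin": b, "state": st, "n": n,
                "proportion": (n / total) if total else np.nan,
            })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Three-step sequences
# ---------------------------------------------------------------------------

@dataclass
class ThreeStepSequence:
    trigger: BehaviorEvent
    si1: SocialInteraction
    si2: SocialInteraction
    sequence_type: int
    same_female: bool
    fight_followed: bool = False

    def __post_init__(self) -> None:
        if self.sequence_type not in (1, 2, 3, 4):
            raise ValueError("sequence_type must be 1-4")


def classify_three_step(sequences: Sequence[TriggeredSequence],
                        interactions: Sequence[SocialInteraction],
                        ) -> list[ThreeStepSequence]:
    """Type the (trigger, first SI, second SI) triples.

    For each aggression-triggered sequence, the second SI is the next SI
    (either male) starting at or after the first SI's onset, before the
    next aggressive trigger, and not already used by another three-step
    sequence. Triples whose two SIs involve the same male fall outside the
    four-type taxonomy and are skipped, as are sequences with no second SI.
    """
    agg_seqs = [s for s in sequences if s.trigger.is_aggressive]
    agg_seqs.sort(key=lambda s: s.trigger.start_frame)
    trigger_starts = sorted(s.trigger.start_frame for s in agg_seqs)
    sis = sorted(interactions, key=lambda s: s.start_frame)
    used: set[int] = set()
    out: list[ThreeStepSequence] = []
    for seq in agg_seqs:
        # window ends at the next aggressive trigger after this one
        i = np.searchsorted(trigger_starts, seq.trigger.start_frame, "right")
        window_end = trigger_starts[i] if i < len(trigger_starts) else np.inf
        si2 = None
        for j, cand in enumerate(sis):
            if cand.start_frame < seq.si.start_frame:
                continue
            if cand.start_frame >= window_end:
                break
            if cand is seq.si or j in used:
                continue
            si2 = cand
            used.add(j)
            break
        if si2 is None or si2.male_id == seq.si.male_id:
            continue
        same = si2.female_id == seq.si.female_id
        if seq.partner_state == "aggressed":
            stype = 1 if same else 3
        elif seq.partner_state == "aggressor":
            stype = 2 if same else 4
        else:
            continue
        out.append(ThreeStepSequence(
            trigger=seq.trigger, si1=seq.si, si2=si2,
            sequence_type=stype, same_female=same,
        ))
    return out


# ---------------------------------------------------------------------------
# Phase-normalized distance profiles
# ---------------------------------------------------------------------------

_PHASES = ("agg", "gap", "si", "post")


@dataclass
class PhaseProfileSet:
    """Phase-normalized inter-individual distance profiles.

    ``profiles[dyad][phase]`` is an (n_sequences, L) array of distances (cm)
    linearly interpolated onto a common grid whose length L is the longest
    instance of that phase; rows from sequences whose phase was empty are
    NaN. ``points`` holds the distances at the landmark times (1 s after SI
    start; 1, 2 and 3 s after SI end) per sequence and dyad.
    """

    profiles: dict[str, dict[str, np.ndarray]]
    points: pd.DataFrame

    def summary(self, dyad: str, phase: str) -> pd.DataFrame:
        """Median and IQR across sequences at each normalized grid point."""
        mat = self.profiles[dyad][phase]
        with np.errstate(all="ignore"):
            return pd.DataFrame({
                "median": np.nanmedian(mat, axis=0),
                "q25": np.nanpercentile(mat, 25, axis=0),
                "q75": np.nanpercentile(mat, 75, axis=0),
            })


def _dyad_distance(t1: Trajectory, t2: Trajectory, start: int, end: int
                   ) -> np.ndarray:
    i0 = t1.index_of(start)
    i1 = i0 + (end - start)
    j0 = t2.index_of(start)
    j1 = j0 + (end - start)
    return np.hypot(t1.x[i0:i1] - t2.x[j0:j1], t1.y[i0:i1] - t2.y[j0:j1])


def _interp_to(series: np.ndarray, length: int) -> np.ndarray:
    """Linear interpolation onto ``length`` points, endpoints preserved."""
    if series.size == 0:
        return np.full(length, np.nan)
    if series.size == 1:
        return np.full(length, series[0])
    xi = np.linspace(0.0, series.size - 1.0, length)
    return np.interp(xi, np.arange(series.size), series)


def phase_profiles(three_step: Sequence[ThreeStepSequence],
                   trajectories: dict[str, Trajectory],
                   fps: float = 30.0,
                   post_window_s: float = 5.0) -> PhaseProfileSet:
    """Distance profiles over the four sequence phases.

    Phases per sequence: the aggressive bout (``agg``), the gap between the
    bout's end and the first SI (``gap``; empty when the SI began during the
    bout), the first SI (``si``) and a ``post_window_s``-second
    post-interaction window (``post``). Dyads tracked: aggressor-female and
    aggressed-female (the first SI's female), plus male-male for type-1
    sequences. Each phase is normalized to its longest instance.
    """
    dyad_series: dict[str, dict[str, list[np.ndarray]]] = {
        d: {p: [] for p in _PHASES}
        for d in ("aggressor_female", "aggressed_female", "male_male")
    }
    point_rows = []
    n_frames = len(next(iter(trajectories.values()))) if trajectories else 0

    for k, ts in enumerate(three_step):
        trig, si1 = ts.trigger, ts.si1
        female = si1.female_id
        agr, agd = trig.aggressor_id, trig.aggressed_id
        dyads = {
            "aggressor_female": (agr, female),
            "aggressed_female": (agd, female),
        }
        if ts.sequence_type == 1:
            dyads["male_male"] = (agr, agd)
        windows = {
            "agg": (trig.start_frame, trig.end_frame),
            "gap": (trig.end_frame, max(trig.end_frame, si1.start_frame)),
            "si": (si1.start_frame, si1.end_frame),
            "post": (si1.end_frame,
                     min(si1.end_frame + int(round(post_window_s * fps)),
                         n_frames)),
        }
        for dyad, (id1, id2) in dyads.items():
            t1, t2 = trajectories[id1], trajectories[id2]
            for phase, (s, e) in windows.items():
                dyad_series[dyad][phase].append(
                    _dyad_distance(t1, t2, s, e) if e > s
                    else np.empty(0))
            for label, frame in (
                ("si_start+1s", si1.start_frame + int(fps)),
                ("si_end+1s", si1.end_frame + int(fps)),
                ("si_end+2s", si1.end_frame + 2 * int(fps)),
                ("si_end+3s", si1.end_frame + 3 * int(fps)),
            ):
                if 0 <= frame < n_frames:
                    d = _dyad_distance(t1, t2, frame, frame + 1)[0]
                    point_rows.append({
                        "sequence_index": k,
                        "sequence_type": ts.sequence_type,
                        "dyad": dyad, "time_label": label,
                        "distance_cm": float(d),
                    })

    profiles: dict[str, dict[str, np.ndarray]] = {}
    for dyad, by_phase in dyad_series.items():
        profiles[dyad] = {}
        for phase, series_list in by_phase.items():
            if not series_list:
                profiles[dyad][phase] = np.empty((0, 0))
                continue
            L = max((s.size for s in series_list), default=0)
            if L == 0:
                profiles[dyad][phase] = np.empty((len(series_list), 0))
                continue
            profiles[dyad][phase] = np.vstack(
                [_interp_to(s, L) for s in series_list])
    points = pd.DataFrame(point_rows, columns=[
        "sequence_index", "sequence_type", "dyad", "time_label",
        "distance_cm"])
    return PhaseProfileSet(profiles=profiles, points=points)


# ---------------------------------------------------------------------------
# Fight association
# ---------------------------------------------------------------------------

def fights_following(three_step: Sequence[ThreeStepSequence],
                     fight_events: Sequence[BehaviorEvent],
                     fps: float = 30.0,
                     window_s: Optional[float] = None) -> pd.DataFrame:
    """Fight frequency after type-1 vs pooled type-2/3/4 sequences.

    A fight is attributed to a three-step sequence when it starts at or
    after the second SI's end and before the next aggressive trigger (or
    within ``window_s`` seconds of the second SI's end when a fixed horizon
    is given). Sets ``fight_followed`` on the sequences and returns one row
    per group (``type1`` and ``other``) with counts and the percentage of
    sequences followed by at least one fight.
    """
    fights = sorted((e for e in fight_events if e.label == "fight"),
                    key=lambda e: e.start_frame)
    fight_starts = np.array([e.start_frame for e in fights])
    trigger_starts = np.array(sorted(
        ts.trigger.start_frame for ts in three_step))
    for ts in three_step:
        lo = ts.si2.end_frame
        if window_s is not None:
            hi = lo + window_s * fps
        else:
            i = np.searchsorted(trigger_starts, ts.trigger.start_frame,
                                "right")
            hi = trigger_starts[i] if i < len(trigger_starts) else np.inf
        k = np.searchsorted(fight_starts, lo, "left")
        ts.fight_followed = bool(k < len(fight_starts)
                                 and fight_starts[k] < hi)
    rows = []
    for name, group in (
        ("type1", [t for t in three_step if t.sequence_type == 1]),
        ("other", [t for t in three_step if t.sequence_type != 1]),
    ):
        n = len(group)
        nf = sum(t.fight_followed for t in group)
        rows.append({
            "group": name, "n_sequences": n, "n_with_fight": nf,
            "pct_with_fight": (100.0 * nf / n) if n else np.nan,
        })
    return pd.DataFrame(rows)
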
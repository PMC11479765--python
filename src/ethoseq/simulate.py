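"""Synthetic arena recordings with planted ground truth.

The generator emulates the study conditions the analysis pipeline assumes:
4 mice (2 males, 2 females) in a 76.2 x 76.2 cm arena recorded at
30 frames/s for 5 h. It emits

* per-frame poses (fitted ellipse + nose) for every mouse,
* a behavior-event table (chase, flee, walk, investigate, fight) as a
  perfect classifier would produce it, and
* ground truth: which male-female approach episode was caused by which
  aggressive bout, the planted initiator, and the planted three-step
  sequence types.

Baseline movement is an Ornstein-Uhlenbeck speed process with diffusing
heading and specular wall reflection. Scripted kernels override the baseline
for the mice taking part in an event. After each aggressive bout each male
independently approaches a female with his state's probability (aggressed
vs aggressor), after a state-specific latency, for a state-specific
duration; with probability ``p_follow_same_female`` the second male's
approach targets the same female, which plants a type-1 (bait-and-switch)
sequence.

So that every detected social interaction corresponds to a planted episode,
non-engaged opposite-sex pairs are actively kept apart (avoidance steering
plus a hard minimum-separation clamp at 12.5 cm, just beyond the maximal
social-ellipse reach). Approaching males contact the female from behind,
which also pins down the planted initiator (the male).

Random draws are consumed in a fixed documented order (aggressive schedule,
approach plans, control events, then the frame loop), so a seed fully
determines a recording.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .interactions import DEFAULT_EXTENSION_CM, SocialEllipse, ellipses_overlap
from .types import (
    ArenaSpec,
    BehaviorEvent,
    MouseInfo,
    RecordingBundle,
    Trajectory,
)

__all__ = [
    "SyntheticConfig",
    "PlantedEpisode",
    "GroundTruth",
    "generate_recording",
    "generate_cohort",
]

TWO_PI = 2.0 * math.pi


def _wrap_angle(theta: float) -> float:
    t = (theta + math.pi) % TWO_PI - math.pi
    return math.pi if t == -math.pi else t


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for one synthetic recording.

    Defaults emulate the published recordings: a 76.2 cm square arena at
    30 fps for 5 h, two males and two females, ~43 aggressive bouts/h split
    roughly 3:1 chase:flee, and a state-dependent tendency for the aggressed
    male to approach a female sooner and more briefly than the aggressor.
    The default approach probabilities put ~62% of aggression-triggered
    interactions on the aggressed male (difference index about -0.25), and
    ``p_follow_same_female`` is set so type-1 (bait-and-switch) sequences
    account for about 53% of typed sequences.
    """

    arena: ArenaSpec = field(default_factory=ArenaSpec)
    n_frames: int = 5 * 3600 * 30
    seed: int = 0
    n_males: int = 2
    n_females: int = 2

    # Baseline movement (OU speed, diffusing heading)
    mean_speed_cm_s: float = 8.0
    speed_sigma_cm_s: float = 4.0
    speed_relaxation_s: float = 1.0
    heading_diffusion_rad2_s: float = 1.5

    # Body ellipse (cm)
    a_cm: float = 3.0
    b_cm: float = 1.5

    # Behavior rates (events/h) and log-normal duration medians/sigmas (s)
    chase_rate_per_h: float = 34.8
    flee_rate_per_h: float = 12.2
    walk_rate_per_h: float = 60.0      # per male
    investigate_rate_per_h: float = 20.0
    fight_rate_per_h: float = 4.0      # background fights
    chase_duration_median_s: float = 1.5
    flee_duration_median_s: float = 1.0
    walk_duration_median_s: float = 1.5
    investigate_duration_median_s: float = 2.0
    fight_duration_median_s: float = 1.5
    duration_sigma: float = 0.4
    p_male1_aggressor: float = 0.75
    min_trigger_gap_s: float = 25.0

    # State-dependent post-aggression approach effect
    p_approach_aggressed: float = 0.40
    p_approach_aggressor: float = 0.36
    latency_median_aggressed_s: float = 1.2
    latency_median_aggressor_s: float = 3.5
    latency_sigma: float = 0.8
    si_duration_median_aggressed_s: float = 1.5
    si_duration_median_aggressor_s: float = 2.5
    si_duration_sigma: float = 0.5
    p_second_si: float = 0.7
    p_follow_same_female: float = 0.855
    follow_latency_median_s: float = 1.5
    p_fight_after_type1: float = 0.05
    p_fight_after_other: float = 0.30
    feasibility_slack_s: float = 10.0

    # Interaction geometry / steering
    extension_cm: float = DEFAULT_EXTENSION_CM
    approach_speed_cm_s: float = 30.0
    engage_offset_cm: float = 2.0
    avoid_radius_cm: float = 16.0
    min_separation_cm: float = 12.5

    def __post_init__(self) -> None:
        for name in ("p_approach_aggressed", "p_approach_aggressor",
                     "p_second_si", "p_follow_same_female",
                     "p_fight_after_type1", "p_fight_after_other",
                     "p_male1_aggressor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        for name in ("chase_rate_per_h", "flee_rate_per_h", "walk_rate_per_h",
                     "investigate_rate_per_h", "fight_rate_per_h"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")

    @property
    def fps(self) -> float:
        return self.arena.fps

    @property
    def is_null(self) -> bool:
        """True iff aggressed/aggressor parameters are equal (no effect)."""
        return (
            self.p_approach_aggressed == self.p_approach_aggressor
            and self.latency_median_aggressed_s == self.latency_median_aggressor_s
            and self.si_duration_median_aggressed_s
            == self.si_duration_median_aggressor_s
        )

    def null_mode(self) -> "SyntheticConfig":
        """The matched no-effect configuration: both states get the averaged
        approach probability and identical latency/duration distributions."""
        p = 0.5 * (self.p_approach_aggressed + self.p_approach_aggressor)
        lat = math.sqrt(self.latency_median_aggressed_s
                        * self.latency_median_aggressor_s)
        dur = math.sqrt(self.si_duration_median_aggressed_s
                        * self.si_duration_median_aggressor_s)
        return replace(
            self,
            p_approach_aggressed=p, p_approach_aggressor=p,
            latency_median_aggressed_s=lat, latency_median_aggressor_s=lat,
            si_duration_median_aggressed_s=dur,
            si_duration_median_aggressor_s=dur,
            p_fight_after_type1=self.p_fight_after_other,
        )


@dataclass
class PlantedEpisode:
    """One planted male-female approach episode and its realized bout."""

    male_id: str
    female_id: str
    trigger_index: int          # index into the aggressive-trigger list
    order: int                  # 1 = first SI after the trigger, 2 = second
    male_state: str             # aggressor | aggressed
    desired_start_frame: int
    planned_duration_frames: int
    start_frame: int = -1       # realized (first overlap frame)
    end_frame: int = -1         # realized (half-open)
    initiator: str = "male"

    @property
    def realized(self) -> bool:
        return self.start_frame >= 0 and self.end_frame > self.start_frame


@dataclass
class GroundTruth:
    """Planted events, episodes, trigger pairings and sequence types."""

    events: list[BehaviorEvent]
    episodes: list[PlantedEpisode]
    #: aggressive-trigger index -> episode index of its first SI
    pairings: dict[int, int]
    #: aggressive-trigger index -> planted three-step type (1-4)
    sequence_types: dict[int, int]
    #: aggressive-trigger indices followed by a planted fight
    fights_after: set[int] = field(default_factory=set)
    n_retries: int = 0


# ---------------------------------------------------------------------------
# Scheduling
# ---------------------------------------------------------------------------

@dataclass
class _ApproachPlan:
    male: str
    female: str
    trigger_index: int
    order: int
    male_state: str
    start_wait_frame: int       # when the controller becomes active
    desired_start_frame: int
    duration_frames: int
    after_episode: Optional[int] = None  # planted order-2 follows episode idx
    fight_after: bool = False
    fight_duration_frames: int = 0


class _BusyBook:
    """Per-mouse reserved intervals (half-open, frames)."""

    def __init__(self, mouse_ids):
        self.busy = {m: [] for m in mouse_ids}

    def free(self, mouse_id: str, start: int, end: int) -> bool:
        return all(e0 >= end or e1 <= start for e0, e1 in self.busy[mouse_id])

    def reserve(self, mouse_id: str, start: int, end: int) -> None:
        self.busy[mouse_id].append((start, end))


def _lognormal_frames(rng, median_s: float, sigma: float, fps: float) -> int:
    return max(2, int(round(rng.lognormal(math.log(median_s), sigma) * fps)))


def _build_schedule(config: SyntheticConfig, rng):
    """Draw the full event schedule and approach plans.

    Returns (aggressive_triggers, other_events, approach_plans, book).
    Aggressive bouts form the spine (renewal process with a minimum gap);
    post-aggression approaches are planted only when they fit before the
    next trigger with slack; walks/investigations/background fights are
    rejection-sampled into the remaining free time.
    """
    fps = config.fps
    n = config.n_frames
    males = [f"M{i+1}" for i in range(config.n_males)]
    females = [f"F{i+1}" for i in range(config.n_females)]
    mouse_ids = males + females
    book = _BusyBook(mouse_ids)

    # 1. aggressive spine (chase/flee renewal process)
    agg_rate = config.chase_rate_per_h + config.flee_rate_per_h
    triggers: list[BehaviorEvent] = []
    if agg_rate > 0 and len(males) >= 2:
        mean_gap = 3600.0 / agg_rate * fps
        min_gap = config.min_trigger_gap_s * fps
        t = rng.exponential(mean_gap)
        while t < n:
            dur_label = "chase" if rng.random() < (
                config.chase_rate_per_h / agg_rate) else "flee"
            median = (config.chase_duration_median_s if dur_label == "chase"
                      else config.flee_duration_median_s)
            dur = _lognormal_frames(rng, median, config.duration_sigma, fps)
            start = int(t)
            end = start + dur
            if end >= n - int(2 * fps):
                break
            aggressor, aggressed = (males[0], males[1]) if (
                rng.random() < config.p_male1_aggressor) else (males[1], males[0])
            if dur_label == "chase":
                ev = BehaviorEvent("chase", aggressor, aggressed, start, end,
                                   confidence=0.9)
            else:
                ev = BehaviorEvent("flee", aggressed, aggressor, start, end,
                                   confidence=0.9)
            triggers.append(ev)
            book.reserve(aggressor, start, end)
            book.reserve(aggressed, start, end)
            t = end + max(rng.exponential(mean_gap), min_gap)

    # 2. post-aggression approach plans
    plans: list[_ApproachPlan] = []
    slack = int(config.feasibility_slack_s * fps)
    for i, trig in enumerate(triggers):
        next_start = triggers[i + 1].start_frame if i + 1 < len(triggers) else n
        t_end = trig.end_frame
        drawn = []
        for state, mid, p, lat_med, dur_med in (
            ("aggressed", trig.aggressed_id, config.p_approach_aggressed,
             config.latency_median_aggressed_s,
             config.si_duration_median_aggressed_s),
            ("aggressor", trig.aggressor_id, config.p_approach_aggressor,
             config.latency_median_aggressor_s,
             config.si_duration_median_aggressor_s),
        ):
            # draws are consumed unconditionally so null/effect cohorts with
            # the same seed share the same aggressive schedule
            u = rng.random()
            lat = rng.lognormal(math.log(lat_med), config.latency_sigma)
            dur = max(8, _lognormal_frames(rng, dur_med,
                                           config.si_duration_sigma, fps))
            fem = females[rng.integers(len(females))]
            if u < p:
                drawn.append((state, mid, int(t_end + lat * fps), dur, fem))
        u_second = rng.random()
        u_follow = rng.random()
        follow_lat = rng.lognormal(math.log(config.follow_latency_median_s),
                                   config.latency_sigma)
        u_fight = rng.random()
        fight_dur = _lognormal_frames(rng, config.fight_duration_median_s,
                                      config.duration_sigma, fps)
        second_state = None
        if len(drawn) == 2:
            drawn.sort(key=lambda d: d[2])
            (s1, m1, t1, d1, f1), (s2, m2, t2, d2, f2) = drawn
            f2 = f1 if u_follow < config.p_follow_same_female else (
                [f for f in females if f != f1][0] if len(females) > 1 else f1)
            t2 = max(t2, t1 + d1 + int(follow_lat * fps))
            first = (s1, m1, t1, d1, f1)
            second = (s2, m2, t2, d2, f2)
            second_state = s2
        elif len(drawn) == 1:
            s1, m1, t1, d1, f1 = drawn[0]
            first = (s1, m1, t1, d1, f1)
            second = None
            if u_second < config.p_second_si:
                other_male = trig.aggressor_id if m1 == trig.aggressed_id \
                    else trig.aggressed_id
                second_state = ("aggressor" if other_male == trig.aggressor_id
                                else "aggressed")
                dur_med2 = (config.si_duration_median_aggressor_s
                            if second_state == "aggressor"
                            else config.si_duration_median_aggressed_s)
                d2 = max(8, _lognormal_frames(rng, dur_med2,
                                              config.si_duration_sigma, fps))
                f2 = f1 if u_follow < config.p_follow_same_female else (
                    [f for f in females if f != f1][0]
                    if len(females) > 1 else f1)
                t2 = t1 + d1 + int(follow_lat * fps)
                second = (second_state, other_male, t2, d2, f2)
        else:
            continue

        s1, m1, t1, d1, f1 = first
        end1 = t1 + d1
        if second is not None:
            s2, m2, t2, d2, f2 = second
            end2 = t2 + d2
            fight = u_fight < (config.p_fight_after_type1
                               if (s1 == "aggressed" and f2 == f1)
                               else config.p_fight_after_other)
            horizon = end2 + (fight_dur if fight else 0) + slack
            if horizon >= next_start or horizon >= n:
                second = None
                fight = False
        if second is None:
            fight = False
            if end1 + slack >= next_start or end1 + slack >= n:
                continue

        plans.append(_ApproachPlan(
            male=m1, female=f1, trigger_index=i, order=1, male_state=s1,
            start_wait_frame=t_end, desired_start_frame=t1,
            duration_frames=d1,
        ))
        book.reserve(m1, t_end, end1 + int(2 * fps))
        if second is not None:
            s2, m2, t2, d2, f2 = second
            plans.append(_ApproachPlan(
                male=m2, female=f2, trigger_index=i, order=2, male_state=s2,
                start_wait_frame=t1 + d1, desired_start_frame=t2,
                duration_frames=d2,
                fight_after=fight,
                fight_duration_frames=fight_dur if fight else 0,
            ))
            book.reserve(m2, t1 + d1, t2 + d2 + int(2 * fps))
            if fight:
                # reserve an estimated window; realized start is dynamic
                for mm in males:
                    book.reserve(mm, t2 + d2,
                                 t2 + d2 + fight_dur + int(6 * fps))

    # 3. control behaviors in the remaining free time
    other: list[BehaviorEvent] = []
    hours = n / fps / 3600.0

    def place(label, participants, median_s, n_events, confidence,
              actor=None, recipient=None):
        for _ in range(n_events):
            dur = _lognormal_frames(rng, median_s, config.duration_sigma, fps)
            for _attempt in range(100):
                start = int(rng.integers(0, max(1, n - dur)))
                if all(book.free(m, start - int(fps), start + dur + int(fps))
                       for m in participants):
                    for m in participants:
                        book.reserve(m, start, start + dur)
                    other.append(BehaviorEvent(
                        label, actor or participants[0],
                        recipient if recipient is not None else (
                            participants[1] if len(participants) > 1 else None),
                        start, start + dur, confidence=confidence))
                    break

    for mid in males:
        place("walk", [mid], config.walk_duration_median_s,
              rng.poisson(config.walk_rate_per_h * hours), 1.5, actor=mid,
              recipient=None)
    if len(males) >= 2:
        n_inv = rng.poisson(config.investigate_rate_per_h * hours)
        for _ in range(n_inv):
            a, b = (males[0], males[1]) if rng.random() < 0.5 else (
                males[1], males[0])
            place("investigate", [a, b], config.investigate_duration_median_s,
                  1, 0.15, actor=a, recipient=b)
        place_n = rng.poisson(config.fight_rate_per_h * hours)
        for _ in range(place_n):
            place("fight", [males[0], males[1]],
                  config.fight_duration_median_s, 1, 2.0,
                  actor=males[0], recipient=males[1])

    return males, females, triggers, other, plans


# ---------------------------------------------------------------------------
# Motion synthesis
# ---------------------------------------------------------------------------

class _Mouse:
    __slots__ = ("mid", "x", "y", "theta", "speed", "mode", "kernel")

    def __init__(self, mid, x, y, theta, speed):
        self.mid = mid
        self.x = x
        self.y = y
        self.theta = theta
        self.speed = speed
        self.mode = "baseline"
        self.kernel = None


def _reflect(x, y, theta, w, h):
    if x < 0:
        x = -x
        theta = math.pi - theta
    elif x > w:
        x = 2 * w - x
        theta = math.pi - theta
    if y < 0:
        y = -y
        theta = -theta
    elif y > h:
        y = 2 * h - y
        theta = -theta
    return x, y, _wrap_angle(theta)


def _overlap(config, m1: _Mouse, m2: _Mouse) -> bool:
    e1 = SocialEllipse(m1.x, m1.y, m1.theta,
                       config.a_cm + config.extension_cm, config.b_cm)
    e2 = SocialEllipse(m2.x, m2.y, m2.theta,
                       config.a_cm + config.extension_cm, config.b_cm)
    return ellipses_overlap(e1, e2)


def _simulate_motion(config: SyntheticConfig, rng, males, females, triggers,
                     other_events, plans):
    """Frame loop: baseline OU wander + scripted kernels.

    Returns (pos arrays, realized episodes, realized dynamic fight events,
    canceled static events).
    """
    fps = config.fps
    dt = 1.0 / fps
    n = config.n_frames
    w, h = config.arena.bounds
    mouse_ids = males + females
    n_mice = len(mouse_ids)
    male_set = set(males)

    X = np.empty((n, n_mice))
    Y = np.empty((n, n_mice))
    TH = np.empty((n, n_mice))

    mice = {}
    for mid in mouse_ids:
        mice[mid] = _Mouse(
            mid,
            rng.uniform(0.15 * w, 0.85 * w),
            rng.uniform(0.15 * h, 0.85 * h),
            rng.uniform(-math.pi, math.pi),
            max(0.0, rng.normal(config.mean_speed_cm_s,
                                config.speed_sigma_cm_s)),
        )

    # static kernels by start frame
    static = []
    for ev in triggers:
        static.append(ev)
    for ev in other_events:
        if ev.label in ("investigate", "fight"):
            static.append(ev)
        elif ev.label == "walk":
            static.append(ev)
    static.sort(key=lambda e: e.start_frame)
    static_i = 0
    canceled: set[int] = set()

    episodes: list[PlantedEpisode] = []
    # plans keyed by activation frame
    plans_sorted = sorted(plans, key=lambda p: p.start_wait_frame)
    plan_i = 0
    # pending order-2 plans waiting for their order-1 episode to finish
    dynamic_fights: list[BehaviorEvent] = []
    pending_fight: list[tuple] = []  # (event, start frame, trigger index)
    fights_after: set[int] = set()

    engaged_pairs: set[frozenset] = set()  # clamp/avoidance exemptions

    def terminate_kernel(m: _Mouse, frame: int) -> None:
        """Free a mouse from its current kernel (aggressive triggers win)."""
        k = m.kernel
        if isinstance(k, BehaviorEvent):
            for p in (k.actor_id, k.recipient_id):
                if p and mice[p].kernel is k:
                    mice[p].mode = "baseline"
                    mice[p].kernel = None
        elif k is not None:
            ep = k.episode
            if ep.start_frame >= 0 and ep.end_frame < 0:
                ep.end_frame = frame
            engaged_pairs.discard(frozenset((m.mid, k.plan.female)))
            m.mode = "baseline"
            m.kernel = None

    tau = config.speed_relaxation_s
    mu = config.mean_speed_cm_s
    sig_s = config.speed_sigma_cm_s * math.sqrt(2.0 * dt / tau)
    sig_th = math.sqrt(config.heading_diffusion_rad2_s * dt)

    class _Approach:
        __slots__ = ("plan", "phase", "engage_left", "episode")

        def __init__(self, plan, episode):
            self.plan = plan
            self.phase = "wait"
            self.engage_left = plan.duration_frames
            self.episode = episode

    def baseline_step(m: _Mouse, frame: int):
        m.speed += -(m.speed - mu) * dt / tau + sig_s * rng.normal()
        if m.speed < 0.0:
            m.speed = 0.0
        m.theta = _wrap_angle(m.theta + sig_th * rng.normal())
        # avoidance of non-engaged opposite-sex mice
        mysex_male = m.mid in male_set
        nearest_d, away = None, None
        for om in mice.values():
            if om is m or ((om.mid in male_set) == mysex_male):
                continue
            if frozenset((m.mid, om.mid)) in engaged_pairs:
                continue
            d = math.hypot(m.x - om.x, m.y - om.y)
            if d < config.avoid_radius_cm and (nearest_d is None or d < nearest_d):
                nearest_d = d
                away = math.atan2(m.y - om.y, m.x - om.x)
        if nearest_d is not None:
            # turn gradually toward the escape direction (no instant spins)
            turn = _wrap_angle(away - m.theta)
            m.theta = _wrap_angle(
                m.theta + max(-0.35, min(0.35, turn)) + 0.05 * rng.normal())
            m.speed = max(m.speed, 15.0)
        nx = m.x + m.speed * dt * math.cos(m.theta)
        ny = m.y + m.speed * dt * math.sin(m.theta)
        m.x, m.y, m.theta = _reflect(nx, ny, m.theta, w, h)

    def steer_to(m: _Mouse, tx, ty, speed):
        d = math.hypot(tx - m.x, ty - m.y)
        m.theta = math.atan2(ty - m.y, tx - m.x)
        step = min(d, speed * dt)
        m.x, m.y, m.theta = _reflect(m.x + step * math.cos(m.theta),
                                     m.y + step * math.sin(m.theta),
                                     m.theta, w, h)
        m.speed = step / dt

    for frame in range(n):
        # activate approach plans
        while plan_i < len(plans_sorted) and \
                plans_sorted[plan_i].start_wait_frame <= frame:
            plan = plans_sorted[plan_i]
            plan_i += 1
            ep = PlantedEpisode(
                male_id=plan.male, female_id=plan.female,
                trigger_index=plan.trigger_index, order=plan.order,
                male_state=plan.male_state,
                desired_start_frame=plan.desired_start_frame,
                planned_duration_frames=plan.duration_frames,
            )
            episodes.append(ep)
            if mice[plan.male].kernel is not None:
                terminate_kernel(mice[plan.male], frame)
            mice[plan.male].mode = "approach"
            mice[plan.male].kernel = _Approach(plan, ep)

        # activate static kernels; aggressive triggers interrupt anything
        while static_i < len(static) and \
                static[static_i].start_frame == frame:
            ev = static[static_i]
            static_i += 1
            participants = [ev.actor_id] + (
                [ev.recipient_id] if ev.recipient_id else [])
            if ev.label in ("chase", "flee"):
                for p in participants:
                    if mice[p].mode != "baseline":
                        terminate_kernel(mice[p], frame)
            elif any(mice[p].mode != "baseline" for p in participants):
                canceled.add(id(ev))
                continue
            for p in participants:
                mice[p].mode = ev.label
                mice[p].kernel = ev

        # start pending dynamic fights
        for item in list(pending_fight):
            ev, start, ti = item
            if frame >= start:
                pending_fight.remove(item)
                ms = [mice[ev.actor_id], mice[ev.recipient_id]]
                if all(m.mode == "baseline" for m in ms):
                    ev2 = BehaviorEvent(ev.label, ev.actor_id, ev.recipient_id,
                                        frame,
                                        min(frame + ev.duration_frames(), n),
                                        confidence=ev.confidence)
                    if ev2.end_frame > ev2.start_frame + 1:
                        dynamic_fights.append(ev2)
                        fights_after.add(ti)
                        for m in ms:
                            m.mode = "fight"
                            m.kernel = ev2

        moved: set[str] = set()

        # scripted kernels first (they may position partners)
        for mid in mouse_ids:
            m = mice[mid]
            if m.mode == "baseline" or mid in moved:
                continue
            k = m.kernel
            if isinstance(k, BehaviorEvent):
                if frame >= k.end_frame:
                    for p in (k.actor_id, k.recipient_id):
                        if p and mice[p].kernel is k:
                            mice[p].mode = "baseline"
                            mice[p].kernel = None
                    baseline_step(m, frame)
                    moved.add(mid)
                    continue
                if k.label in ("chase", "flee"):
                    aggressor = mice[k.aggressor_id]
                    aggressed = mice[k.aggressed_id]
                    if k.label == "chase":
                        # aggressed runs, aggressor tracks 8 cm behind
                        aggressed.theta = _wrap_angle(
                            aggressed.theta + 0.25 * rng.normal())
                        aggressed.speed = 30.0
                        nx = aggressed.x + 30.0 * dt * math.cos(aggressed.theta)
                        ny = aggressed.y + 30.0 * dt * math.sin(aggressed.theta)
                        aggressed.x, aggressed.y, aggressed.theta = _reflect(
                            nx, ny, aggressed.theta, w, h)
                        gx = aggressed.x - 8.0 * math.cos(aggressed.theta)
                        gy = aggressed.y - 8.0 * math.sin(aggressed.theta)
                        aggressor.x = min(max(gx, 0.0), w)
                        aggressor.y = min(max(gy, 0.0), h)
                        aggressor.theta = math.atan2(aggressed.y - aggressor.y,
                                                     aggressed.x - aggressor.x)
                        aggressor.speed = 30.0
                    else:
                        # aggressor stationary, aggressed flees
                        aggressor.speed = 0.0
                        away = math.atan2(aggressed.y - aggressor.y,
                                          aggressed.x - aggressor.x)
                        aggressed.theta = _wrap_angle(
                            away + 0.2 * rng.normal())
                        aggressed.speed = 30.0
                        nx = aggressed.x + 30.0 * dt * math.cos(aggressed.theta)
                        ny = aggressed.y + 30.0 * dt * math.sin(aggressed.theta)
                        aggressed.x, aggressed.y, aggressed.theta = _reflect(
                            nx, ny, aggressed.theta, w, h)
                    moved.add(k.aggressor_id)
                    moved.add(k.aggressed_id)
                elif k.label == "walk":
                    m.theta = _wrap_angle(m.theta + 0.1 * rng.normal())
                    m.speed = 12.0
                    nx = m.x + 12.0 * dt * math.cos(m.theta)
                    ny = m.y + 12.0 * dt * math.sin(m.theta)
                    m.x, m.y, m.theta = _reflect(nx, ny, m.theta, w, h)
                    moved.add(mid)
                elif k.label in ("investigate", "fight"):
                    m1, m2 = mice[k.actor_id], mice[k.recipient_id]
                    d = math.hypot(m1.x - m2.x, m1.y - m2.y)
                    if d > 3.0:
                        steer_to(m1, m2.x, m2.y, 25.0)
                        steer_to(m2, m1.x, m1.y, 25.0)
                    else:
                        jitter = 0.30 if k.label == "fight" else 0.03
                        for mm in (m1, m2):
                            mm.theta = _wrap_angle(
                                mm.theta + 0.4 * rng.normal())
                            mm.x, mm.y, mm.theta = _reflect(
                                mm.x + jitter * rng.normal(),
                                mm.y + jitter * rng.normal(),
                                mm.theta, w, h)
                            mm.speed = jitter / dt
                    moved.add(k.actor_id)
                    moved.add(k.recipient_id)
            elif isinstance(k, _Approach):
                fem = mice[k.plan.female]
                pair = frozenset((mid, k.plan.female))
                female_busy = any(k.plan.female in p and mid not in p
                                  for p in engaged_pairs)
                if k.phase == "wait":
                    d = math.hypot(fem.x - m.x, fem.y - m.y)
                    # 1.6 slack factor allows for routing around the female
                    travel = 1.6 * max(0.0, d - config.engage_offset_cm) \
                        / config.approach_speed_cm_s
                    remaining = (k.plan.desired_start_frame - frame) * dt
                    if remaining <= travel and not female_busy:
                        k.phase = "approach"
                        engaged_pairs.add(pair)
                    else:
                        baseline_step(m, frame)
                if k.phase == "approach":
                    # close in from the female's rear so the male's front
                    # half-ellipse makes first contact and initiation is
                    # unambiguously his
                    rx, ry = m.x - fem.x, m.y - fem.y
                    d = math.hypot(rx, ry)
                    bx, by = -math.cos(fem.theta), -math.sin(fem.theta)
                    cosang = (rx * bx + ry * by) / d if d > 1e-9 else 1.0
                    orbit_r = 14.0  # just beyond the 12 cm overlap reach
                    # hold at orbit distance while another male is engaged
                    # with this female; close in only once she is free
                    if female_busy or (d < orbit_r + 6.0
                                       and cosang < math.cos(0.6)):
                        # orbit around the female toward her rear cone
                        cur = math.atan2(ry, rx)
                        rear = math.atan2(by, bx)
                        diff = _wrap_angle(rear - cur)
                        step_ang = math.copysign(min(abs(diff), 0.12), diff)
                        ang = cur + step_ang
                        m.x = min(max(fem.x + orbit_r * math.cos(ang), 0.0), w)
                        m.y = min(max(fem.y + orbit_r * math.sin(ang), 0.0), h)
                        m.theta = math.atan2(fem.y - m.y, fem.x - m.x)
                        m.speed = config.approach_speed_cm_s
                    else:
                        tx = fem.x + (config.engage_offset_cm) * bx
                        ty = fem.y + (config.engage_offset_cm) * by
                        steer_to(m, tx, ty, config.approach_speed_cm_s)
                        m.theta = math.atan2(fem.y - m.y, fem.x - m.x)
                    # the engage transition is decided on final positions in
                    # the post-movement pass below
                elif k.phase == "engage":
                    # track a point just behind the female at capped speed
                    tx = fem.x - config.engage_offset_cm * math.cos(fem.theta)
                    ty = fem.y - config.engage_offset_cm * math.sin(fem.theta)
                    steer_to(m, tx, ty, config.approach_speed_cm_s)
                    m.theta = math.atan2(fem.y - m.y, fem.x - m.x)
                    k.engage_left -= 1
                    if k.engage_left <= 0:
                        k.phase = "exit"
                elif k.phase == "exit":
                    away = math.atan2(m.y - fem.y, m.x - fem.x)
                    m.theta = away
                    step = 40.0 * dt
                    m.x, m.y, m.theta = _reflect(
                        m.x + step * math.cos(away),
                        m.y + step * math.sin(away), away, w, h)
                    m.speed = 40.0
                    # release is decided on final positions below
                moved.add(mid)

        # baseline everyone else
        for mid in mouse_ids:
            if mid not in moved:
                baseline_step(mice[mid], frame)

        # hard separation clamp for non-engaged opposite-sex pairs
        def place_apart(anchor: _Mouse, mover: _Mouse) -> None:
            """Reposition ``mover`` at least min_separation from ``anchor``,
            sliding along the walls when the radial push would clip."""
            sep = config.min_separation_cm
            dx, dy = mover.x - anchor.x, mover.y - anchor.y
            d0 = math.hypot(dx, dy)
            base = math.atan2(dy, dx) if d0 > 1e-9 else 0.0
            best = (d0, mover.x, mover.y)
            for dang in (0.0, 0.4, -0.4, 0.8, -0.8, 1.2, -1.2, 1.6, -1.6,
                         2.1, -2.1, 2.6, -2.6, math.pi):
                ang = base + dang
                x = min(max(anchor.x + sep * math.cos(ang), 0.0), w)
                y = min(max(anchor.y + sep * math.sin(ang), 0.0), h)
                dd = math.hypot(x - anchor.x, y - anchor.y)
                if dd >= sep - 1e-9:
                    mover.x, mover.y, mover.theta = x, y, _wrap_angle(ang)
                    return
                if dd > best[0]:
                    best = (dd, x, y)
            mover.x, mover.y = best[1], best[2]

        for mm in males:
            a = mice[mm]
            for ff in females:
                if frozenset((mm, ff)) in engaged_pairs:
                    continue
                fmouse = mice[ff]
                d = math.hypot(a.x - fmouse.x, a.y - fmouse.y)
                if d < config.min_separation_cm:
                    a_scripted = a.mode != "baseline"
                    b_scripted = fmouse.mode != "baseline"
                    if b_scripted and not a_scripted:
                        place_apart(fmouse, a)
                    else:
                        # females are never scripted, so the female is the
                        # movable partner in every other case
                        place_apart(a, fmouse)

        # approach-kernel transitions, decided on the same final positions
        # the emitted trajectories (and hence the detector) will contain
        for mid in mouse_ids:
            m = mice[mid]
            k = m.kernel
            if not isinstance(k, _Approach):
                continue
            fem = mice[k.plan.female]
            if k.phase == "approach":
                if _overlap(config, m, fem):
                    k.phase = "engage"
                    k.episode.start_frame = frame
            elif k.phase == "exit":
                if not _overlap(config, m, fem):
                    # bout over: release; from the next frame the separation
                    # clamp keeps the pair apart, so no re-overlap run
                    k.episode.end_frame = frame
                    engaged_pairs.discard(frozenset((mid, k.plan.female)))
                    m.mode = "baseline"
                    m.kernel = None
                    if k.plan.fight_after:
                        fight_start = frame + int(fps)
                        ev = BehaviorEvent(
                            "fight", males[0], males[1], fight_start,
                            fight_start + k.plan.fight_duration_frames,
                            confidence=2.0)
                        pending_fight.append(
                            (ev, fight_start, k.plan.trigger_index))

        for j, mid in enumerate(mouse_ids):
            m = mice[mid]
            X[frame, j] = m.x
            Y[frame, j] = m.y
            TH[frame, j] = m.theta

    # close any episode still open at the end of the recording
    for ep in episodes:
        if ep.start_frame >= 0 and ep.end_frame < 0:
            ep.end_frame = n

    return mouse_ids, X, Y, TH, episodes, dynamic_fights, canceled, fights_after


# ---------------------------------------------------------------------------
# Public API
# ---------------------------------------------------------------------------

def _refine_episode_bounds(episodes, trajectories, config,
                           min_frames: int = 6) -> None:
    """Snap episode bounds to the realized overlap run in the poses.

    The frame loop records provisional bounds from mid-frame positions;
    the definitive bout is the maximal overlap run (same predicate as the
    detector) containing the engagement window. Grazing-contact flickers
    shorter than ``min_frames`` around the onset are invisible to the
    detector and are likewise discarded here.
    """
    from .interactions import _runs, pair_overlap_mask

    n = next(iter(trajectories.values())).frames[-1] + 1 if trajectories \
        else 0
    for ep in episodes:
        if not ep.realized:
            continue
        margin = 150
        w0 = max(0, ep.start_frame - margin)
        w1 = min(n, ep.end_frame + margin)
        tm = trajectories[ep.male_id]
        tf = trajectories[ep.female_id]

        def window(t):
            return Trajectory(
                t.mouse_id, t.frames[w0:w1], t.x[w0:w1], t.y[w0:w1],
                t.theta[w0:w1], t.a[w0:w1], t.b[w0:w1],
                t.nose_x[w0:w1], t.nose_y[w0:w1], fps=t.fps)

        mask = pair_overlap_mask(window(tm), window(tf),
                                 extension_cm=config.extension_cm)
        runs = [(s + w0, e + w0) for s, e in _runs(mask)
                if e - s >= min_frames]
        mid = (ep.start_frame + ep.end_frame) // 2
        containing = [r for r in runs if r[0] <= mid < r[1]]
        if not containing:
            # fall back to the run with the largest overlap with the window
            overlaps = [(min(r[1], ep.end_frame) - max(r[0], ep.start_frame),
                         r) for r in runs]
            overlaps = [(o, r) for o, r in overlaps if o > 0]
            if not overlaps:
                ep.start_frame = ep.end_frame = -1
                continue
            containing = [max(overlaps)[1]]
        ep.start_frame, ep.end_frame = containing[0]


def _derive_ground_truth(triggers, episodes, events) -> GroundTruth:
    by_trigger: dict[int, list[int]] = {}
    for idx, ep in enumerate(episodes):
        if ep.realized:
            by_trigger.setdefault(ep.trigger_index, []).append(idx)
    pairings: dict[int, int] = {}
    types: dict[int, int] = {}
    for ti, idxs in by_trigger.items():
        idxs.sort(key=lambda i: episodes[i].start_frame)
        pairings[ti] = idxs[0]
        if len(idxs) >= 2:
            e1, e2 = episodes[idxs[0]], episodes[idxs[1]]
            if e1.male_id != e2.male_id:
                same = e1.female_id == e2.female_id
                if e1.male_state == "aggressed":
                    types[ti] = 1 if same else 3
                else:
                    types[ti] = 2 if same else 4
    return GroundTruth(events=list(events), episodes=episodes,
                       pairings=pairings, sequence_types=types)


def generate_recording(config: SyntheticConfig,
                       recording_id: str = "sim",
                       with_poses: bool = True
                       ) -> tuple[RecordingBundle, GroundTruth]:
    """Generate one synthetic recording and its ground truth.

    Deterministic for a fixed ``config.seed``. With ``with_poses=False``
    only the event schedule and idealized (desired-time) episodes are
    produced — orders of magnitude faster, for schedule-level statistics
    that do not need trajectories.
    """
    rng = np.random.default_rng(config.seed)
    males, females, triggers, other, plans = _build_schedule(config, rng)
    mice = [MouseInfo(m, "M") for m in males] + \
           [MouseInfo(f, "F") for f in females]

    if with_poses:
        (mouse_ids, X, Y, TH, episodes, dyn_fights, canceled,
         fights_after) = _simulate_motion(
            config, rng, males, females, triggers, other, plans)
        events = [e for e in triggers + other if id(e) not in canceled]
        events += dyn_fights
        events.sort(key=lambda e: (e.start_frame, e.end_frame))
        trajectories = {}
        a = np.full(config.n_frames, config.a_cm)
        b = np.full(config.n_frames, config.b_cm)
        frames = np.arange(config.n_frames)
        for j, mid in enumerate(mouse_ids):
            nose_x = X[:, j] + config.a_cm * np.cos(TH[:, j])
            nose_y = Y[:, j] + config.a_cm * np.sin(TH[:, j])
            trajectories[mid] = Trajectory(
                mid, frames, X[:, j], Y[:, j], TH[:, j], a, b,
                nose_x, nose_y, fps=config.fps)
        _refine_episode_bounds(episodes, trajectories, config)
        gt = _derive_ground_truth(triggers, episodes, events)
        gt.fights_after = fights_after
    else:
        episodes = []
        fights_after = set()
        for plan in plans:
            episodes.append(PlantedEpisode(
                male_id=plan.male, female_id=plan.female,
                trigger_index=plan.trigger_index, order=plan.order,
                male_state=plan.male_state,
                desired_start_frame=plan.desired_start_frame,
                planned_duration_frames=plan.duration_frames,
                start_frame=plan.desired_start_frame,
                end_frame=plan.desired_start_frame + plan.duration_frames,
            ))
            if plan.fight_after:
                fs = plan.desired_start_frame + plan.duration_frames + \
                    int(config.fps)
                other.append(BehaviorEvent(
                    "fight", males[0], males[1], fs,
                    fs + plan.fight_duration_frames, confidence=2.0))
                fights_after.add(plan.trigger_index)
        events = sorted(triggers + other,
                        key=lambda e: (e.start_frame, e.end_frame))
        trajectories = {}
        gt = _derive_ground_truth(triggers, episodes, events)
        gt.fights_after = fights_after

    bundle = RecordingBundle(
        arena=config.arena, mice=mice, trajectories=trajectories,
        events=events, recording_id=recording_id)
    return bundle, gt


def generate_cohort(config: SyntheticConfig, n_recordings: int, seed: int,
                    with_poses: bool = True
                    ) -> list[tuple[RecordingBundle, GroundTruth]]:
    """Generate a cohort of recordings with reproducibly derived seeds."""
    if n_recordings < 1:
        raise ValueError("n_recordings must be >= 1")
    child_seeds = np.random.SeedSequence(seed).generate_state(n_recordings)
    out = []
    for i, cs in enumerate(child_seeds):
        cfg = replace(config, seed=int(cs) % (2**31))
        out.append(generate_recording(cfg, recording_id=f"sim{i+1:02d}",
                                      with_poses=with_poses))
    return out
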
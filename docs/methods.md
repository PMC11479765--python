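# Methods

This note documents the models, conventions and numerical choices behind
`ethoseq`, and what the synthetic-data tests do and do not establish.

## Conventions

Frames are 0-based; every interval is half-open `[start, end)`, so a
duration in seconds is `(end − start)/fps`. Coordinates are centimetres
with the origin at the arena's lower-left corner (x east, y north); the
standard arena is a 76.2 × 76.2 cm square at 30 frames/s, with a cylindrical
arena (68.6 cm diameter) supported for zone and exploration analyses.
Headings are radians in (−π, π]. Instantaneous speed at frame *t* is the
centroid displacement from *t − 1* times fps, with `speed[0]` backfilled
from `speed[1]` so stationarity predicates are total.

## Interaction detection

The social ellipse keeps the body ellipse's center and orientation and
lengthens the semi-major axis by 3 cm (so it extends 3 cm in front of and
behind the animal); the semi-minor axis is unchanged. Overlap of two social
ellipses is decided on 64-vertex polygonal approximations via shapely's
convex-polygon intersection, preceded by two exact bounds: centers farther
apart than the summed semi-majors cannot overlap, centers closer than the
summed semi-minors must. The 64-gon slightly under-covers the true ellipse
(sagitta < 0.01 cm at these axis lengths), so verdicts are only uncertain
for pairs whose minimal clearance is below that margin; a dense
boundary-membership oracle in the test suite quantifies this. An SI bout is
a maximal run of overlapping frames of an opposite-sex pair lasting at
least 6 frames; runs separated by even a single dropout frame are distinct
bouts (no gap merging — configurable nowhere on purpose, so bout counts are
reproducible). A centroid-distance detector (separation ≤ 6 cm, one body
length) is available behind `method="centroid"` for sensitivity analyses;
the ellipse construction is the canonical definition.

## Triggered sequences and typing

A trigger's candidate window runs from its own onset to the next trigger's
onset; the earliest SI in the window forms the sequence, each SI belongs to
at most one trigger, and latency may be negative (SI beginning during the
bout) but an SI can never precede its trigger's onset. No absolute latency
cap is applied by default (`latency_cap_s` exists for sensitivity
analyses). Latency is defined as SI start minus trigger end; this sign
convention makes typical latencies positive.

For three-step typing, SI₂ is the next SI — by either male — starting at or
after SI₁'s onset and before the next aggressive trigger, never reused
across sequences. Triples whose SIs involve the same male fall outside the
four-type taxonomy and are excluded (counted by the caller as the
difference between sequences and typed triples). Phase profiles divide each
sequence into aggressive bout, gap (empty when latency ≤ 0), SI, and a 5 s
post-SI window; each phase is linearly interpolated onto a grid as long as
that phase's longest instance (endpoints preserved exactly), and medians
with IQRs are aggregated per grid point. A fight is attributed to a
sequence if it starts after SI₂ ends and before the next aggressive
trigger; a fixed time horizon is available via `window_s`.

## Circular statistics

The heading-to-partner angle is `atan2(|v₁ × v₂|, v₁ · v₂)` with v₁ the
centroid→nose vector and v₂ the centroid→partner vector, always in [0, π].
The circular median minimizes the mean arc-length distance over the sample
points themselves (ties broken toward the smallest wrapped angle); circular
variance is 1 − R. The two-sample Watson U² statistic is computed from the
cumulative difference of the two empirical CDFs over the pooled circular
order in its variance form, which makes it exactly invariant under joint
rotation; significance comes from random label permutations with
`p = (1 + #{U²_perm ≥ U²_obs}) / (1 + n_perm)`, valid at any permutation
count and sample size (no asymptotic tables).

## Initiator assignment

A mouse is stationary when its speed falls below 0.023 cm/s. This printed
threshold is implausibly slow for grooming detection (≈ 0.0008 cm/frame);
it is implemented as given but configurable. If exactly one partner is
stationary at bout onset, the other initiated. If both are moving, the
initiator is the animal whose front half-ellipse (the half of the social
ellipse on the nose side of the minor axis) first overlaps the partner's
social ellipse; when both animals head toward each other (each
heading-to-partner angle < π/2) and their front overlaps begin within 6
frames of each other, the initiation is mutual. Both-stationary onsets and
onsets with no front overlap in the scan window are undetermined.

## Zones

Five 6 cm-radius zones are used for the post-aggression latency control.
Their centers are not standardized anywhere, so the package places zone 5
at the arena center and zones 1–4 at the midpoints between the center and
the north/east/south/west wall midpoints; all centers are configurable.
Latency runs from the trigger's end frame to the first frame the male's
centroid enters the zone disk (0 if already inside); zones never reached
before the recording ends are excluded from medians and counted.

## Resampling and decoding

The difference index over sequences is
(n_aggressor − n_aggressed)/(total). The subsampling control draws a fixed
number of sequences (default 50) without replacement from every recording,
pools, and recomputes the index 1,000 times; the identity shuffle flips
each trigger's role assignment with probability ½ (order and durations
untouched) and recomputes. Both are z-tested: z = mean/sd of the
distribution for the subsample test, z = (observed − null mean)/null sd for
the shuffle. Decoders use repeated random 75/25 splits (1,000 iterations):
a decision tree (impurity splitting, no depth cap, minimum leaf size 1) for
the two-class state problem and a linear one-vs-one SVM for multiclass
problems; accuracy is compared to chance (100/#classes %) with a one-sided
z on the accuracy distribution, z = (mean − chance)/sd. The sd (not
sd/√n) is used because the iterations resample the same data and are not
independent; the alternative is a one-line change. Size matching subsamples
every class to the smallest class per iteration; time randomization redraws
trigger start times uniformly (durations preserved) and rebuilds sequences
before decoding. Dunn's rank-based post hoc test with Šidák family
correction follows a significant Kruskal–Wallis omnibus; identical paired
samples short-circuit the Wilcoxon wrapper to (W = 0, p = 1).

## Synthetic data generator

The generator's defaults are the study conditions: 2 males + 2 females,
76.2 cm square arena, 30 fps, 5 h; ~43 aggressive bouts/h split roughly 3:1
chase:flee with one male the aggressor in 75% of bouts; walks,
investigations and background fights at fixed hourly rates; log-normal
durations throughout.

Baseline movement is an Ornstein–Uhlenbeck speed process (mean 8 cm/s,
sd 4 cm/s, relaxation 1 s, clipped at zero) with a diffusing heading
(1.5 rad²/s) and specular wall reflection. These values give realistic
coverage of the arena over minutes; no quantitative claim is made that they
match real mouse kinematics. Scripted kernels override the baseline: during
a chase the aggressed runs at 30 cm/s and the aggressor tracks 8 cm behind
(inter-male distance stays within two body lengths); during a flee the
aggressor is stationary and the aggressed runs away; investigations and
fights bring the two males into contact with low- and high-amplitude jitter
respectively; walks are steady solitary locomotion.

After each aggressive bout, each male independently approaches a uniformly
chosen female with his state's probability, after a state-specific
log-normal latency, for a state-specific duration. Defaults:
p(approach | aggressed) = 0.40, p(approach | aggressor) = 0.36, latency
medians 1.2 s vs 3.5 s, SI duration medians 1.5 s vs 2.5 s. These put ~62%
of aggression-triggered SIs on the aggressed male (difference index ≈
−0.23). When a second SI follows (probability 0.7, or automatically when
both males approach), the second male targets the same female with
probability 0.855 — chosen so the type-1 (bait-and-switch) fraction is
≈ 0.53 under the default state asymmetry. Fights follow typed sequences
with probability 0.05 after type 1 and 0.30 after other types. Null mode
equalizes the two states' approach probabilities and distributions and the
fight probabilities; with the same seed, the null and effect configurations
share an identical aggressive-event schedule, because every per-trigger
random draw is consumed whether or not it is used.

Approach kinematics are engineered so the planted structure is exactly
recoverable. Non-engaged opposite-sex pairs are kept apart by avoidance
steering (gradual turns, max 0.35 rad/frame) and a hard minimum-separation
clamp at 12.5 cm — just beyond the 12 cm maximal reach of two social
ellipses — with a wall-aware repositioning search so a cornered mouse can
still be separated. Consequently every detected SI bout corresponds to a
planted episode. An approaching male routes around the female at a 14 cm
orbit into her rear cone, holds there while she is engaged with the other
male, then closes in on a point 2 cm behind her; contact from the rear
makes the male's front half-ellipse the first to overlap and keeps the
female's heading pointed away, so the initiator rule attributes the bout to
the male (planted initiator). Engagement tracks the wandering female at
capped speed for the drawn duration, then the male exits radially at
40 cm/s. Bout start and end transitions are evaluated on the same
end-of-frame poses that are emitted as trajectories, and after simulation
each episode's bounds are snapped to the maximal detector-style overlap run
containing the engagement, so ground-truth bounds equal detector output
bit-for-bit; grazing flickers shorter than the 6-frame minimum around onset
are invisible to both. Scheduling places aggressive bouts as a renewal
process with a 25 s minimum gap and only plants approaches that fit before
the next trigger with 10 s slack; control events are rejection-sampled into
the remaining free time, and an aggressive trigger interrupts any other
activity at its onset.

What the generator does **not** emulate: tracking noise and identity
swaps, spontaneous (non-triggered) male–female interactions, negative
latencies (SIs beginning during the trigger are supported by the analysis
but not planted), biomechanical gait, vocalizations, and drifting behavior
over hours. Passing tests therefore demonstrate that the pipeline recovers
the statistical structure it is designed to detect when that structure is
present and clean — not that real tracking data will be noise-free. The
circular arena is handled by bounding-box wall reflection in the simulator
(zones and exploration handle the circle properly).

## Problem sizes

The test suite and the acceptance script use desk-scale problem sizes
chosen to keep full runs in the tens of seconds while leaving every
statistical conclusion well-powered: 30-minute recordings (5 per cohort)
for pose-level recovery checks, schedule-level 5 h cohorts (11 recordings,
~180 sequences each) for the permutation suite, 100 replicate 4-recording
cohorts for the null calibration, and 1,000 iterations for every
permutation distribution and decoder.
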
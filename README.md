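# ethoseq

Trajectory-based analysis of social behavior sequences in group-housed mice.

When two male and two female mice share an arena, male–male aggression is
followed by a characteristic pattern of opposite-sex contact: the *aggressed*
(chased or fleeing) male tends to reach a female first, briefly, and the
aggressor then engages the same female — a "bait-and-switch" that is
associated with fewer subsequent fights. `ethoseq` implements the complete
quantitative pipeline needed to detect and test this phenomenon from tracked
poses, for behavioral neuroscientists and computational ethologists working
with multi-animal arena recordings:

* **Interaction detection.** Each mouse's fitted body ellipse is extended
  3 cm along the major axis in front of and behind the animal (the *social
  ellipse*); a male–female social interaction (SI) is a maximal run of
  frames with overlapping social ellipses lasting ≥ 6 frames (0.2 s at
  30 frames/s).
* **Triggered sequences.** Each aggressive bout (chase or flee, with
  aggressor/aggressed roles) is paired with the first SI starting in its
  window; the sequence is characterized by latency
  ℓ = (t\_SI,start − t\_trigger,end)/fps (negative when the SI begins during
  the bout), duration, and the partner male's behavioral state.
* **The difference index.**
  `DI = (n_aggressor − n_aggressed) / (n_aggressor + n_aggressed)` over
  sequences; DI < 0 means aggressed males dominate post-aggression contact.
  Significance comes from fixed-size subsampling across recordings and from
  an identity-shuffle permutation null (each trigger's roles flipped with
  probability ½), both z-tested.
* **Decoding.** Repeated 75/25-split decision trees decode the partner's
  state from (latency, duration), with size-matched and time-randomized
  controls; multiclass linear SVMs (one-vs-one) decode hour-of-occurrence
  and three-step sequence type.
* **Three-step taxonomy.** Trigger → SI₁ → SI₂ triples are typed 1–4 by
  which male performs SI₂ and whether it involves the same female; type 1
  (aggressed first, aggressor then same female) is the bait-and-switch.
  Phase-normalized dyadic distance profiles and fight-association rates
  quantify its consequences.
* **Circular statistics.** Heading-to-partner angles
  θ = atan2(|v₁ × v₂|, v₁ · v₂), circular median/variance, and a
  permutation-based two-sample Watson U² test.
* **Synthetic arena simulator.** An Ornstein–Uhlenbeck movement model with
  scripted behavior kernels plants aggressive bouts, state-dependent
  female approaches, three-step sequences and fights with known ground
  truth — every stage of the pipeline is testable without any recording.

## Worked example

Simulate a small cohort (3 recordings of 20 minutes at the default effect
sizes) and run the full pipeline:

```python
from ethoseq.pipeline import PipelineConfig, run_pipeline, simulate_to_disk
from ethoseq.simulate import SyntheticConfig

cfg = PipelineConfig(
    seed=7, n_recordings=3, output_dir="demo_out",
    synthetic=SyntheticConfig(n_frames=20 * 60 * 30),  # 20-minute recordings
)
simulate_to_disk(cfg, "demo_data")
cfg.input_dir = "demo_data"
cfg.subsample_k = 10
report = run_pipeline(cfg)
```

which prints (via the `report` dict):

```
recordings:        3
SI bouts detected: 58
triggered seqs:    33
difference index:  -0.455
shuffle z, p:      -2.58, 0.0099
type-1 fraction:   0.64
decoder observed:  72.6% (chance 50%, z = 1.59)
decoder randomized: 47.6%
```

The negative difference index says aggressed males took most of the
post-aggression female contacts; the identity-shuffle z-test confirms the
asymmetry is tied to the roles rather than the event timing; the decision
tree recovers the partner's state from latency and duration well above the
50% chance level, and collapses to chance once trigger times are
randomized. At the full study scale (11 recordings × 5 h) the same pipeline
gives a difference index near −0.23 with ~62% of sequences involving the
aggressed male and a type-1 fraction near 0.53.

The same stages are available from the shell:

```bash
ethoseq simulate --output-dir demo_data --n-recordings 3 --duration-min 20 --seed 7
ethoseq all --input-dir demo_data --output-dir demo_out --seed 7
```

Outputs are tidy CSVs (`sequences.csv`, `threestep.csv`, `zone_latencies.csv`,
`hour_proportions.csv`, `decoder_accuracies.csv`, `phase_points.csv`, ...)
plus `report.json` and a `provenance.json` run record.

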
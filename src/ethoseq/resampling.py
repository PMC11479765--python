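"""Permutation suite, randomization controls and behavioral-state decoding.

The *difference index* over a set of triggered sequences is

    (n_aggressor_partner - n_aggressed_partner) / (total),

so negative values mean the aggressed male dominates post-aggression
interactions. Controls implemented here:

* subsampling (fixed-size random subsets per recording) to rule out sample
  size effects,
* an identity shuffle (each trigger's aggressor/aggressed assignment flipped
  with probability 1/2) to destroy state linkage while preserving order and
  durations,
* uniform re-draws of event start times (durations preserved) to destroy
  temporal linkage,
* repeated 75/25 split decoders (decision trees for two-class state,
  linear one-vs-one SVMs for multiclass problems) with size-matched and
  time-randomized variants, compared to chance with a z-test on the
  accuracy distribution.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier

from .sequences import ThreeStepSequence, TriggeredSequence
from .types import BehaviorEvent, Trajectory

__all__ = [
    "difference_index",
    "DifferenceIndexResult",
    "subsample_index_distribution",
    "identity_shuffle_null",
    "randomize_event_times",
    "DecoderRun",
    "decode_state",
    "decode_multiclass",
    "state_features",
    "hour_features",
    "agg_kinematics_features",
    "threestep_distance_features",
    "group_stats",
    "StatResult",
    "bonferroni_alpha",
]

_POSITIVE_STATES = {"aggressor", "walker", "investigator"}
_NEGATIVE_STATES = {"aggressed", "non_walker", "investigated"}


def _signs(sequences: Sequence[TriggeredSequence]) -> np.ndarray:
    """+1 for the active-role partner (aggressor/walker/investigator),
    -1 for the passive one."""
    signs = np.empty(len(sequences))
    for i, s in enumerate(sequences):
        if s.partner_state in _POSITIVE_STATES:
            signs[i] = 1.0
        elif s.partner_state in _NEGATIVE_STATES:
            signs[i] = -1.0
        else:
            raise ValueError(f"unknown partner state {s.partner_state!r}")
    return signs


def difference_index(sequences: Sequence[TriggeredSequence]) -> float:
    """Signed difference index in [-1, 1]; negative = aggressed majority."""
    if not sequences:
        raise ValueError("difference index undefined for zero sequences")
    return float(np.mean(_signs(sequences)))


@dataclass
class DifferenceIndexResult:
    observed_index: Optional[float]
    null_distribution: np.ndarray
    z: float
    p: float
    n_iterations: int


def subsample_index_distribution(
        sequences_by_recording: dict[str, Sequence[TriggeredSequence]],
        k: int = 50, n_iter: int = 1000,
        seed: Optional[int] = None) -> DifferenceIndexResult:
    """Distribution of pooled difference indices over random subsamples.

    Each iteration draws ``k`` sequences without replacement from every
    recording, pools them and computes the index; the z-test compares the
    standardized distribution against zero (two-sided).
    """
    for rec, seqs in sequences_by_recording.items():
        if len(seqs) < k:
            raise ValueError(
                f"recording {rec!r} has only {len(seqs)} sequences (< k={k})")
    rng = np.random.default_rng(seed)
    signs = {rec: _signs(seqs) for rec, seqs in sequences_by_recording.items()}
    dist = np.empty(n_iter)
    n_total = k * len(signs)
    for it in range(n_iter):
        total = 0.0
        for s in signs.values():
            idx = rng.choice(s.size, size=k, replace=False)
            total += s[idx].sum()
        dist[it] = total / n_total
    sd = dist.std(ddof=0)
    z = float(dist.mean() / sd) if sd > 0 else (
        0.0 if dist.mean() == 0 else np.inf * np.sign(dist.mean()))
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DifferenceIndexResult(
        observed_index=None, null_distribution=dist, z=z, p=p,
        n_iterations=n_iter)


def identity_shuffle_null(sequences: Sequence[TriggeredSequence],
                          n_iter: int = 1000,
                          seed: Optional[int] = None) -> DifferenceIndexResult:
    """Null distribution of the index under random role flips.

    Each iteration flips every trigger's aggressor/aggressed assignment with
    probability 1/2 (which toggles the sequence's partner state), recomputes
    the index, and the observed index is compared to the null distribution
    with a two-sided z-test.
    """
    signs = _signs(sequences)
    observed = float(signs.mean())
    rng = np.random.default_rng(seed)
    flips = rng.integers(0, 2, size=(n_iter, signs.size)) * 2 - 1
    null = (flips * signs[None, :]).mean(axis=1)
    sd = null.std(ddof=0)
    z = float((observed - null.mean()) / sd) if sd > 0 else 0.0
    p = float(2.0 * stats.norm.sf(abs(z)))
    return DifferenceIndexResult(
        observed_index=observed, null_distribution=null, z=z, p=p,
        n_iterations=n_iter)


def randomize_event_times(events: Sequence[BehaviorEvent],
                          recording_frames: int,
                          seed: Optional[int] = None) -> list[BehaviorEvent]:
    """Redraw event start frames uniformly, preserving durations and roles."""
    rng = np.random.default_rng(seed)
    out = []
    for ev in events:
        dur = ev.duration_frames()
        if dur > recording_frames:
            raise ValueError("event longer than the recording")
        start = int(rng.integers(0, recording_frames - dur + 1))
        out.append(BehaviorEvent(ev.label, ev.actor_id, ev.recipient_id,
                                 start, start + dur, ev.confidence))
    out.sort(key=lambda e: (e.start_frame, e.end_frame))
    return out


# ---------------------------------------------------------------------------
# Decoders
# ---------------------------------------------------------------------------

@dataclass
class DecoderRun:
    condition: str
    feature_names: tuple[str, ...]
    accuracies: np.ndarray  # percent, one per iteration
    chance_level: float     # percent
    mean: float
    sd: float
    z: float
    p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "condition": self.condition,
            "iteration": np.arange(self.accuracies.size),
            "accuracy": self.accuracies,
        })


def _finish_run(condition, feature_names, accs, chance) -> DecoderRun:
    accs = np.asarray(accs, dtype=float)
    mean = float(accs.mean())
    sd = float(accs.std(ddof=0))
    z = (mean - chance) / sd if sd > 0 else (
        0.0 if mean == chance else np.inf * np.sign(mean - chance))
    p = float(stats.norm.sf(z))  # one-sided (above chance)
    return DecoderRun(condition=condition, feature_names=tuple(feature_names),
                      accuracies=accs, chance_level=chance, mean=mean, sd=sd,
                      z=float(z), p=p)


def state_features(sequences: Sequence[TriggeredSequence]
                   ) -> tuple[np.ndarray, np.ndarray]:
    """(latency_s, duration_s) features and partner-state labels."""
    X = np.array([[s.latency_s, s.duration_s] for s in sequences])
    y = np.array([s.partner_state for s in sequences])
    return X, y


def hour_features(sequences: Sequence[TriggeredSequence]
                  ) -> tuple[np.ndarray, np.ndarray]:
    """(latency, duration, partner-identity indicator) and hour-bin labels."""
    males = sorted({s.partner_male_id for s in sequences})
    X = np.array([[s.latency_s, s.duration_s,
                   float(males.index(s.partner_male_id))]
                  for s in sequences])
    y = np.array([s.hour_bin for s in sequences])
    if np.any(y == None):  # noqa: E711
        raise ValueError("hour bins not assigned; run "
                         "hour_binned_state_proportions first")
    return X, y.astype(int)


def agg_kinematics_features(three_step: Sequence[ThreeStepSequence],
                            trajectories: dict[str, Trajectory],
                            fps: float = 30.0
                            ) -> tuple[np.ndarray, np.ndarray]:
    """Mean speed and path length of both males during the aggressive bout."""
    rows, labels = [], []
    for ts in three_step:
        trig = ts.trigger
        feats = []
        for mid in (trig.aggressor_id, trig.aggressed_id):
            t = trajectories[mid]
            i0 = t.index_of(trig.start_frame)
            i1 = t.index_of(trig.end_frame - 1) + 1
            step = np.hypot(np.diff(t.x[i0:i1]), np.diff(t.y[i0:i1]))
            feats.extend([float(step.mean() * fps) if step.size else 0.0,
                          float(step.sum())])
        rows.append(feats)
        labels.append(ts.sequence_type)
    return np.array(rows), np.array(labels)


def threestep_distance_features(three_step: Sequence[ThreeStepSequence],
                                trajectories: dict[str, Trajectory]
                                ) -> tuple[np.ndarray, np.ndarray]:
    """Aggressor-female and aggressed-female distances at six landmarks.

    Landmarks: start and end of the aggressive bout, of the first SI and of
    the second SI (12 features: 6 time points x 2 dyads).
    """
    rows, labels = [], []
    for ts in three_step:
        trig, si1, si2 = ts.trigger, ts.si1, ts.si2
        female = si1.female_id
        frames = [trig.start_frame, trig.end_frame - 1,
                  si1.start_frame, si1.end_frame - 1,
                  si2.start_frame, si2.end_frame - 1]
        feats = []
        for mid in (trig.aggressor_id, trig.aggressed_id):
            t = trajectories[mid]
            tf = trajectories[female]
            for fr in frames:
                i, j = t.index_of(fr), tf.index_of(fr)
                feats.append(float(np.hypot(t.x[i] - tf.x[j],
                                            t.y[i] - tf.y[j])))
        rows.append(feats)
        labels.append(ts.sequence_type)
    return np.array(rows), np.array(labels)


def _split_indices(rng, n: int, frac: float) -> tuple[np.ndarray, np.ndarray]:
    perm = rng.permutation(n)
    n_train = max(1, int(round(frac * n)))
    n_train = min(n_train, n - 1)
    return perm[:n_train], perm[n_train:]


def _size_match(rng, y: np.ndarray) -> np.ndarray:
    """Indices subsampling every class to the smallest class size."""
    classes, counts = np.unique(y, return_counts=True)
    m = counts.min()
    keep = []
    for c in classes:
        idx = np.flatnonzero(y == c)
        keep.append(rng.choice(idx, size=m, replace=False))
    return np.sort(np.concatenate(keep))


def decode_state(sequences: Sequence[TriggeredSequence],
                 features: tuple[str, ...] = ("latency_s", "duration_s"),
                 split: float = 0.75, n_iter: int = 1000,
                 condition: str = "observed",
                 seed: Optional[int] = None) -> DecoderRun:
    """Repeated-split decision-tree decoding of the partner's state.

    Per iteration: a random 75/25 train/test split, an axis-aligned decision
    tree (no depth cap, minimum leaf size 1) fit on the training features,
    and test accuracy in percent. ``condition="size_matched"`` subsamples
    the majority class to the minority size before each split;
    ``"randomized"`` labels a run on sequences rebuilt from time-randomized
    triggers (mechanically identical to ``"observed"``).
    """
    if len(sequences) < 20:
        raise ValueError("decode_state needs at least 20 sequences")
    X = np.array([[getattr(s, f) for f in features] for s in sequences])
    y = np.array([s.partner_state for s in sequences])
    if np.unique(y).size != 2:
        raise ValueError("decode_state requires exactly two classes")
    if condition not in ("observed", "size_matched", "randomized"):
        raise ValueError(f"unknown condition {condition!r}")
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    for it in range(n_iter):
        if condition == "size_matched":
            keep = _size_match(rng, y)
            Xi, yi = X[keep], y[keep]
        else:
            Xi, yi = X, y
        tr, te = _split_indices(rng, len(yi), split)
        clf = DecisionTreeClassifier(
            random_state=int(rng.integers(2**31)))
        clf.fit(Xi[tr], yi[tr])
        accs[it] = 100.0 * float(np.mean(clf.predict(Xi[te]) == yi[te]))
    return _finish_run(condition, features, accs, chance=50.0)


def decode_multiclass(X: np.ndarray, y: np.ndarray,
                      n_iter: int = 1000, split: float = 0.75,
                      size_matched: bool = False,
                      chance: Optional[float] = None,
                      condition: str = "observed",
                      seed: Optional[int] = None) -> DecoderRun:
    """Repeated-split multiclass decoding with a linear one-vs-one SVM.

    Accuracy per iteration on a random 75/25 split; ``size_matched``
    subsamples all classes to the smallest class per iteration. Chance
    defaults to ``100 / n_classes`` percent.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("decode_multiclass requires at least two classes")
    if size_matched and counts.min() < 4:
        raise ValueError("size-matched decoding needs >= 4 examples per class")
    if chance is None:
        chance = 100.0 / classes.size
    rng = np.random.default_rng(seed)
    accs = np.empty(n_iter)
    for it in range(n_iter):
        if size_matched:
            keep = _size_match(rng, y)
            Xi, yi = X[keep], y[keep]
        else:
            Xi, yi = X, y
        tr, te = _split_indices(rng, len(yi), split)
        if np.unique(yi[tr]).size < 2:
            accs[it] = 100.0 * float(
                np.mean(yi[te] == yi[tr][0]))
            continue
        clf = SVC(kernel="linear", decision_function_shape="ovo")
        clf.fit(Xi[tr], yi[tr])
        accs[it] = 100.0 * float(np.mean(clf.predict(Xi[te]) == yi[te]))
    return _finish_run(condition, ("features",), accs, chance=chance)


# ---------------------------------------------------------------------------
# Standard test wrappers
# ---------------------------------------------------------------------------

@dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    posthoc: Optional[pd.DataFrame] = None


def bonferroni_alpha(alpha: float, n_comparisons: int) -> float:
    """Family-wise adjusted per-comparison alpha level."""
    return alpha / n_comparisons


def _dunn_sidak(groups: Sequence[np.ndarray]) -> pd.DataFrame:
    """Dunn's rank-based post hoc z-tests with Sidak family correction."""
    pooled = np.concatenate(groups)
    n = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    splits = np.cumsum([g.size for g in groups])[:-1]
    group_ranks = np.split(ranks, splits)
    mean_ranks = [r.mean() for r in group_ranks]
    m = len(groups)
    n_pairs = m * (m - 1) // 2
    rows = []
    for i in range(m):
        for j in range(i + 1, m):
            se = np.sqrt((n * (n + 1) / 12.0 - tie_term)
                         * (1.0 / groups[i].size + 1.0 / groups[j].size))
            z = (mean_ranks[i] - mean_ranks[j]) / se
            p = 2.0 * stats.norm.sf(abs(z))
            p_adj = 1.0 - (1.0 - min(p, 1.0)) ** n_pairs
            rows.append({"group1": i, "group2": j, "z": float(z),
                         "p": float(p), "p_adjusted": float(min(p_adj, 1.0))})
    return pd.DataFrame(rows)


def group_stats(samples, test: str, **kwargs) -> StatResult:
    """Thin wrappers over the standard tests used throughout the analyses.

    ``samples`` is (x, y) for paired tests, a list of groups for the
    Kruskal-Wallis route, observed counts for the chi-square, or
    (values, reference) for the z-tests on permutation/accuracy
    distributions.
    """
    if test == "wilcoxon_signed_rank":
        x, y = (np.asarray(s, dtype=float) for s in samples)
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        if np.all(x == y):
            # zero differences throughout: no evidence against symmetry
            return StatResult(test, 0.0, 1.0)
        stat, p = stats.wilcoxon(x, y, zero_method="wilcox", **kwargs)
        return StatResult(test, float(stat), float(p))
    if test == "kruskal_wallis_dunn_sidak":
        groups = [np.asarray(g, dtype=float) for g in samples]
        stat, p = stats.kruskal(*groups)
        posthoc = _dunn_sidak(groups) if p < kwargs.get("alpha", 0.05) else None
        return StatResult(test, float(stat), float(p), posthoc=posthoc)
    if test == "chi_square":
        counts = np.asarray(samples, dtype=float)
        stat, p = stats.chisquare(counts, **kwargs)
        return StatResult(test, float(stat), float(p))
    if test in ("one_sided_z", "two_sided_z"):
        values, reference = samples
        values = np.asarray(values, dtype=float)
        sd = values.std(ddof=0)
        z = (values.mean() - reference) / sd if sd > 0 else 0.0
        p = stats.norm.sf(z) if test == "one_sided_z" \
            else 2.0 * stats.norm.sf(abs(z))
        return StatResult(test, float(z), float(p))
    raise ValueError(f"unknown test {test!r}")
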
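"""Rule-based, subject-exclusive, class-balanced train/val/test splitting.

The procedure mirrors how inter-patient ECG evaluation has to be set up:
(1) optionally thin out the over-represented Normal class with an even
per-subject quota; (2) bar subjects with (almost) no arrhythmic beats from
train/val — they carry no class-balance information and are better spent
measuring generalization; (3) assign whole subjects to train/val/test with
a greedy minimizer of a class-balance objective, so no patient ever spans
two splits.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .core import Segment
from .errors import CapacityError, CoverageError, InfeasibleError, ParameterError

SPLIT_NAMES = ("train", "val", "test")


@dataclass
class SplitConfig:
    """Split fractions (by segment share), Normal-downsampling total,
    non-arrhythmic exclusion threshold and shuffling seed."""

    fractions: dict[str, float] = field(
        default_factory=lambda: {"train": 0.6, "val": 0.2, "test": 0.2}
    )
    normal_remove_total: int = 0
    theta: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        fr = [self.fractions.get(s, 0.0) for s in SPLIT_NAMES]
        if any(f <= 0 for f in fr) or abs(sum(fr) - 1.0) > 1e-9:
            raise ParameterError("split fractions must be > 0 and sum to 1")
        if not 0 <= self.theta < 1:
            raise ParameterError("theta must lie in [0, 1)")


@dataclass
class SplitAssignment:
    """subject -> split mapping plus balance diagnostics."""

    assignment: dict[str, str]
    fractions: dict[str, float]
    class_counts: dict[str, dict[int, int]]
    balance_score: float

    def subjects(self, split: str) -> set[str]:
        return {s for s, v in self.assignment.items() if v == split}

    def to_json(self) -> str:
        return json.dumps(
            {
                "assignment": self.assignment,
                "fractions": self.fractions,
                "class_counts": {k: {str(c): n for c, n in v.items()}
                                 for k, v in self.class_counts.items()},
                "balance_score": self.balance_score,
            },
            indent=2,
            sort_keys=True,
        )


def downsample_normals(
    segments: list[Segment], total_remove: int, seed: int = 0
) -> list[Segment]:
    """Remove ``total_remove`` Normal segments, spread evenly over subjects.

    Each subject loses an equal quota ``floor(total_remove / n_subjects)``;
    the remainder is redistributed round-robin to subjects that still have
    normals to give. Within a subject the removed segments are drawn
    uniformly at random under ``seed``. Non-Normal segments are untouched.
    """
    if total_remove == 0:
        return list(segments)
    by_subject: dict[str, list[int]] = {}
    for i, s in enumerate(segments):
        if s.label == 0:
            by_subject.setdefault(s.subject_id, []).append(i)
    available = sum(len(v) for v in by_subject.values())
    if total_remove > available:
        raise CapacityError(
            f"cannot remove {total_remove} normals; only {available} present"
        )
    # even quotas, redistributing what over-quota'd subjects cannot supply
    quota = {sid: 0 for sid in by_subject}
    remaining = total_remove
    while remaining > 0:
        open_subjects = sorted(sid for sid in quota if quota[sid] < len(by_subject[sid]))
        per = max(remaining // len(open_subjects), 1)
        for sid in open_subjects:
            take = min(per, len(by_subject[sid]) - quota[sid], remaining)
            quota[sid] += take
            remaining -= take
            if remaining == 0:
                break

    rng = np.random.default_rng(seed)
    drop: set[int] = set()
    for sid in sorted(by_subject):
        idx = by_subject[sid]
        drop.update(rng.choice(idx, size=quota[sid], replace=False).tolist())
    return [s for i, s in enumerate(segments) if i not in drop]


def exclude_nonarrhythmic(
    segments: list[Segment], theta: float = 0.01
) -> tuple[set[str], set[str]]:
    """Subjects eligible for train/val vs all subjects.

    A subject is barred from train/val iff its arrhythmic fraction
    (labels 1-3 over all its segments) is strictly below ``theta``; barred
    subjects remain eligible for test.
    """
    if not 0 <= theta < 1:
        raise ParameterError("theta must lie in [0, 1)")
    totals: dict[str, int] = {}
    arrhythmic: dict[str, int] = {}
    for s in segments:
        totals[s.subject_id] = totals.get(s.subject_id, 0) + 1
        if s.label != 0:
            arrhythmic[s.subject_id] = arrhythmic.get(s.subject_id, 0) + 1
    all_subjects = set(totals)
    eligible = {sid for sid in all_subjects
                if arrhythmic.get(sid, 0) / totals[sid] >= theta}
    return eligible, all_subjects


def balance_score(
    counts: dict[str, np.ndarray], fractions: dict[str, float]
) -> float:
    """Deviation of per-split class counts from a perfectly proportional split.

    ``sum_{split,class} |count(split,class) - fraction(split)*count(class)|``
    normalized by the total segment count; 0 means every split holds exactly
    its share of every class.
    """
    pooled = sum(counts.values())
    total = float(pooled.sum())
    if total == 0:
        return 0.0
    dev = 0.0
    for split in SPLIT_NAMES:
        dev += float(np.abs(counts[split] - fractions[split] * pooled).sum())
    return dev / total


def _subject_class_counts(segments: list[Segment], n_classes: int = 4) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for s in segments:
        out.setdefault(s.subject_id, np.zeros(n_classes, dtype=int))[s.label] += 1
    return out


def _exhaustive_assign(
    per_subject: dict[str, np.ndarray],
    eligible: set[str],
    config: SplitConfig,
) -> dict[str, str]:
    """Vectorized enumeration of all eligibility-honoring partitions."""
    sids = sorted(per_subject)
    n = len(sids)
    mat = np.stack([per_subject[s] for s in sids])  # (n, 4)
    combos = np.stack(
        np.meshgrid(*[np.arange(3)] * n, indexing="ij"), axis=-1
    ).reshape(-1, n)
    ok = np.ones(len(combos), dtype=bool)
    for j, sid in enumerate(sids):
        if sid not in eligible:
            ok &= combos[:, j] == SPLIT_NAMES.index("test")
    for s in range(3):
        ok &= (combos == s).any(axis=1)
    combos = combos[ok]
    if not len(combos):
        raise InfeasibleError("no partition satisfies the eligibility constraints")
    pooled = mat.sum(axis=0)
    total = float(pooled.sum())
    dev = np.zeros(len(combos))
    for s, name in enumerate(SPLIT_NAMES):
        counts = (combos[:, :, None] == s) * mat[None, :, :]
        dev += np.abs(counts.sum(axis=1) - config.fractions[name] * pooled).sum(axis=1)
    best = combos[int(np.argmin(dev / total))]
    return {sid: SPLIT_NAMES[k] for sid, k in zip(sids, best)}


def assign_subjects(segments: list[Segment], config: SplitConfig | None = None) -> SplitAssignment:
    """Subject-exclusive assignment minimizing the balance score.

    Cohorts of at most 10 subjects are solved exactly by enumeration.
    Larger cohorts use a greedy pass — subjects placed largest-first (ties
    broken by id), each into the split minimizing the running balance
    score — polished by steepest-descent single moves and pairwise swaps.
    Subjects barred from train/val by the ``theta`` rule are forced into
    test. A fix-up guarantees no split ends empty.
    """
    config = config or SplitConfig()
    per_subject = _subject_class_counts(segments)
    if len(per_subject) < 3:
        raise InfeasibleError("need at least 3 subjects for a 3-way split")
    eligible, _ = exclude_nonarrhythmic(segments, config.theta)

    if len(per_subject) <= 10:
        assignment = _exhaustive_assign(per_subject, eligible, config)
        counts = {s: np.zeros(4, dtype=int) for s in SPLIT_NAMES}
        for sid, split in assignment.items():
            counts[split] += per_subject[sid]
        return SplitAssignment(
            assignment=assignment,
            fractions=dict(config.fractions),
            class_counts={s: {c: int(counts[s][c]) for c in range(4)}
                          for s in SPLIT_NAMES},
            balance_score=balance_score(counts, config.fractions),
        )

    order = sorted(per_subject, key=lambda sid: (-per_subject[sid].sum(), sid))
    counts = {s: np.zeros(4, dtype=int) for s in SPLIT_NAMES}
    assignment: dict[str, str] = {}
    for sid in order:
        options = SPLIT_NAMES if sid in eligible else ("test",)
        best_split, best = None, np.inf
        for split in options:
            counts[split] += per_subject[sid]
            score = balance_score(counts, config.fractions)
            counts[split] -= per_subject[sid]
            if score < best:
                best_split, best = split, score
        assignment[sid] = best_split
        counts[best_split] += per_subject[sid]

    # no split may end empty: move the cheapest eligible subject in
    for split in SPLIT_NAMES:
        if any(v == split for v in assignment.values()):
            continue
        movable = [sid for sid in order
                   if (split == "test" or sid in eligible)
                   and list(assignment.values()).count(assignment[sid]) > 1]
        best_sid, best = None, np.inf
        for sid in movable:
            src = assignment[sid]
            counts[src] -= per_subject[sid]
            counts[split] += per_subject[sid]
            score = balance_score(counts, config.fractions)
            counts[split] -= per_subject[sid]
            counts[src] += per_subject[sid]
            if score < best:
                best_sid, best = sid, score
        if best_sid is None:
            raise InfeasibleError(f"no subject can populate split {split!r}")
        counts[assignment[best_sid]] -= per_subject[best_sid]
        counts[split] += per_subject[best_sid]
        assignment[best_sid] = split

    # steepest-descent refinement: single-subject moves and pairwise swaps
    def apply(moves):
        for sid, dst in moves:
            counts[assignment[sid]] -= per_subject[sid]
            counts[dst] += per_subject[sid]
            assignment[sid] = dst

    def allowed(sid, dst):
        return dst == "test" or sid in eligible

    for _ in range(200):
        best_moves, best = None, balance_score(counts, config.fractions) - 1e-12
        split_sizes = {s: sum(1 for v in assignment.values() if v == s)
                       for s in SPLIT_NAMES}
        candidates = []
        for sid in order:
            src = assignment[sid]
            if split_sizes[src] > 1:
                candidates.extend(
                    [(sid, dst)] for dst in SPLIT_NAMES
                    if dst != src and allowed(sid, dst)
                )
        for i, s1 in enumerate(order):
            for s2 in order[i + 1 :]:
                a, b = assignment[s1], assignment[s2]
                if a != b and allowed(s1, b) and allowed(s2, a):
                    candidates.append([(s1, b), (s2, a)])
        for moves in candidates:
            undo = [(sid, assignment[sid]) for sid, _ in moves]
            apply(moves)
            score = balance_score(counts, config.fractions)
            apply(undo)
            if score < best:
                best_moves, best = moves, score
        if best_moves is None:
            break
        apply(best_moves)

    return SplitAssignment(
        assignment=assignment,
        fractions=dict(config.fractions),
        class_counts={s: {c: int(counts[s][c]) for c in range(4)} for s in SPLIT_NAMES},
        balance_score=balance_score(counts, config.fractions),
    )


def materialize_splits(
    segments: list[Segment], assignment: SplitAssignment, seed: int = 0
) -> tuple[list[Segment], list[Segment], list[Segment]]:
    """Partition segments by subject; shuffle the training set under ``seed``."""
    buckets: dict[str, list[Segment]] = {s: [] for s in SPLIT_NAMES}
    for seg in segments:
        split = assignment.assignment.get(seg.subject_id)
        if split is None:
            raise CoverageError(f"subject {seg.subject_id} missing from assignment")
        buckets[split].append(seg)
    rng = np.random.default_rng(seed)
    train = buckets["train"]
    perm = rng.permutation(len(train))
    return [train[i] for i in perm], buckets["val"], buckets["test"]
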
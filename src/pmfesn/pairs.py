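"""Stage-2 balancing: balanced same/dissimilar training-pair construction.

After stage 1 every class holds n samples, so the same-class pair pool has
S = sum_m C(n_m, 2) members, while the dissimilar pool is far larger. To
keep the two losses balanced *and* spread the dissimilar pairs evenly over
label combinations, all S same-class pairs are kept, and from each of the
Z = C(M, 2) unordered label pairs exactly floor(S/Z) distinct cross-class
pairs are drawn uniformly without replacement. The combined set is shuffled
and split 7:3 (stratified by pair label) into training and validation pairs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb
from typing import Sequence

import numpy as np

from .preprocess import PreparedSample

__all__ = [
    "SamplePair",
    "PairSet",
    "count_same_pairs",
    "label_pairs",
    "build_pairs",
    "split_train_val",
]


@dataclass
class SamplePair:
    """Two distinct samples with a binary same-class label (1 = same mRS)."""

    a: PreparedSample
    b: PreparedSample
    pair_label: int

    def __post_init__(self) -> None:
        if self.a.case_id == self.b.case_id:
            raise ValueError("a pair must consist of two distinct samples")
        same = int(self.a.mrs == self.b.mrs)
        if self.pair_label != same:
            raise ValueError(
                f"pair_label {self.pair_label} inconsistent with labels ({self.a.mrs}, {self.b.mrs})"
            )

    @property
    def key(self) -> frozenset:
        return frozenset((self.a.case_id, self.b.case_id))


@dataclass
class PairSet:
    pairs: list
    n_same: int
    n_dissimilar: int
    allocation: dict  # unordered label pair -> number of cross-class pairs


def count_same_pairs(class_counts: "dict | Sequence[int]") -> int:
    """S = sum over classes of C(n_m, 2) (0 for classes with n_m < 2)."""
    values = class_counts.values() if isinstance(class_counts, dict) else class_counts
    if any(int(n) < 0 for n in values):
        raise ValueError("class counts must be non-negative")
    return sum(comb(int(n), 2) for n in values)


def label_pairs(labels: Sequence[int]) -> tuple[list, int]:
    """All Z = C(|L|, 2) unordered label pairs of a label set."""
    uniq = sorted(set(int(l) for l in labels))
    if len(uniq) < 2:
        raise ValueError("need at least two distinct labels")
    lp = [tuple(p) for p in combinations(uniq, 2)]
    return lp, len(lp)


def build_pairs(samples: Sequence[PreparedSample], seed: int = 0) -> PairSet:
    """Construct the balanced training pair set from a stage-1-balanced set.

    Same-class pairs: every unordered within-class pair, labelled 1.
    Dissimilar pairs: for each label pair, floor(S/Z) distinct cross-class
    pairs sampled uniformly without replacement, labelled 0. When the
    allocation floors to zero (tiny toy sets) the dissimilar set is empty
    and a warning is emitted.
    """
    samples = list(samples)
    by_class: dict = {}
    for s in samples:
        by_class.setdefault(s.mrs, []).append(s)
    counts = {m: len(v) for m, v in by_class.items()}
    s_total = count_same_pairs(counts)
    lp, z = label_pairs(list(counts))
    alloc = s_total // z
    rng = np.random.default_rng(seed)

    same = [
        SamplePair(a, b, 1)
        for m in sorted(by_class)
        for a, b in combinations(by_class[m], 2)
    ]
    assert len(same) == s_total

    if alloc == 0:
        warnings.warn(
            f"floor(S/Z) = 0 for S={s_total}, Z={z}; dissimilar pair set is empty",
            stacklevel=2,
        )
    dissimilar = []
    allocation = {}
    for la, lb in lp:
        pool_a, pool_b = by_class[la], by_class[lb]
        available = len(pool_a) * len(pool_b)
        if alloc > available:
            raise ValueError(
                f"label pair ({la},{lb}): need {alloc} cross pairs but only {available} exist"
            )
        chosen = rng.choice(available, size=alloc, replace=False)
        for flat in chosen:
            a = pool_a[int(flat) // len(pool_b)]
            b = pool_b[int(flat) % len(pool_b)]
            dissimilar.append(SamplePair(a, b, 0))
        allocation[(la, lb)] = alloc

    pairs = same + dissimilar
    order = rng.permutation(len(pairs))
    pairs = [pairs[i] for i in order]
    return PairSet(pairs=pairs, n_same=len(same), n_dissimilar=len(dissimilar), allocation=allocation)


def split_train_val(pairset: PairSet, train_frac: float = 0.7, seed: int = 0) -> tuple[list, list]:
    """Disjoint 7:3 train/validation split, stratified by pair label.

    The total training size is round(train_frac * n); per-label sizes start
    at floor(train_frac * n_label) and the remainder goes to the labels with
    the largest fractional parts, so each label is split 7:3 up to rounding.
    """
    pairs = list(pairset.pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two pairs to split")
    rng = np.random.default_rng(seed)
    by_label: dict = {}
    for p in pairs:
        by_label.setdefault(p.pair_label, []).append(p)
    n = len(pairs)
    target = int(round(train_frac * n))
    labels = sorted(by_label)
    base = {l: int(np.floor(train_frac * len(by_label[l]))) for l in labels}
    frac = {l: train_frac * len(by_label[l]) - base[l] for l in labels}
    leftover = target - sum(base.values())
    for l in sorted(labels, key=lambda l: -frac[l]):
        if leftover <= 0:
            break
        room = len(by_label[l]) - base[l]
        take = min(room, leftover)
        base[l] += take
        leftover -= take
    train, val = [], []
    for l in labels:
        group = by_label[l]
        order = rng.permutation(len(group))
        k = base[l]
        train.extend(group[i] for i in order[:k])
        val.extend(group[i] for i in order[k:])
    return train, val
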
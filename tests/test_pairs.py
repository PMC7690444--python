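from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import make_class_samples
from pmfesn.pairs import (
    build_pairs,
    count_same_pairs,
    label_pairs,
    split_train_val,
)

SHAPE = (6, 6, 3)


def brute_force_same_pairs(counts):
    """Enumerate all unordered within-class pairs explicitly."""
    total = 0
    for n in counts:
        total += len(list(combinations(range(n), 2)))
    return total


class TestCounting:
    @pytest.mark.parametrize(
        "counts, expected",
        [((2, 2, 2, 2, 2), 5), ((14, 14, 14, 14, 14), 455), ((1, 3), 3), ((0, 5), 10)],
    )
    def test_same_pair_formula(self, counts, expected):
        assert count_same_pairs(counts) == expected
        assert count_same_pairs(counts) == brute_force_same_pairs(counts)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            count_same_pairs([-1, 2])

    @pytest.mark.parametrize(
        "labels, z", [([0, 1, 2, 3, 4], 10), ([0, 1], 1), ([0, 1, 2], 3)]
    )
    def test_label_pair_count(self, labels, z):
        lp, got = label_pairs(labels)
        assert got == z and len(set(lp)) == z

    def test_label_pair_enumeration(self):
        lp, _ = label_pairs([0, 1, 2])
        assert lp == [(0, 1), (0, 2), (1, 2)]

    def test_single_label_rejected(self):
        with pytest.raises(ValueError):
            label_pairs([3])


class TestBuildPairs:
    def test_tiny_balanced_set_has_empty_dissimilar_pool(self):
        samples = make_class_samples((2, 2, 2, 2, 2), shape=SHAPE)
        with pytest.warns(UserWarning, match="floor"):
            ps = build_pairs(samples, seed=0)
        assert ps.n_same == 5 and ps.n_dissimilar == 0

    def test_two_classes_of_three(self):
        samples = make_class_samples((3, 3), shape=SHAPE)
        ps = build_pairs(samples, seed=0)
        assert ps.n_same == 6 and ps.n_dissimilar == 6
        assert ps.allocation == {(0, 1): 6}

    def test_all_same_pairs_enumerated(self):
        samples = make_class_samples((3, 4), shape=SHAPE)
        ps = build_pairs(samples, seed=1)
        same_keys = {p.key for p in ps.pairs if p.pair_label == 1}
        by_class = {0: [s for s in samples if s.mrs == 0], 1: [s for s in samples if s.mrs == 1]}
        expected = {
            frozenset((a.case_id, b.case_id))
            for grp in by_class.values()
            for a, b in combinations(grp, 2)
        }
        assert same_keys == expected

    def test_pair_labels_consistent_and_unique(self):
        samples = make_class_samples((4, 4, 4), shape=SHAPE)
        ps = build_pairs(samples, seed=2)
        keys = [p.key for p in ps.pairs]
        assert len(keys) == len(set(keys))  # no duplicates, unordered
        for p in ps.pairs:
            assert p.a.case_id != p.b.case_id
            assert p.pair_label == int(p.a.mrs == p.b.mrs)

    def test_equal_allocation_across_label_pairs(self):
        samples = make_class_samples((5, 5, 5, 5, 5), shape=SHAPE)
        ps = build_pairs(samples, seed=3)
        assert len(set(ps.allocation.values())) == 1
        s = count_same_pairs((5,) * 5)
        assert set(ps.allocation.values()) == {s // 10}
        assert ps.n_dissimilar <= ps.n_same

    def test_dissimilar_equals_same_when_divisible(self):
        samples = make_class_samples((3, 3), shape=SHAPE)  # S=6, Z=1
        ps = build_pairs(samples, seed=0)
        assert ps.n_dissimilar == ps.n_same

    def test_seeded_determinism(self):
        samples = make_class_samples((4, 4, 4), shape=SHAPE)
        k1 = [p.key for p in build_pairs(samples, seed=5).pairs]
        k2 = [p.key for p in build_pairs(samples, seed=5).pairs]
        assert k1 == k2

    @settings(deadline=None, max_examples=20, derandomize=True)
    @given(
        n_classes=st.integers(2, 5),
        n_per=st.integers(2, 5),
        seed=st.integers(0, 100),
    )
    def test_invariants_hold_for_balanced_inputs(self, n_classes, n_per, seed):
        samples = make_class_samples((n_per,) * n_classes, shape=SHAPE)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ps = build_pairs(samples, seed=seed)
        s = count_same_pairs((n_per,) * n_classes)
        _, z = label_pairs(range(n_classes))
        assert ps.n_same == s
        assert set(ps.allocation.values()) == {s // z}
        assert ps.n_dissimilar == z * (s // z) <= ps.n_same
        keys = [p.key for p in ps.pairs]
        assert len(keys) == len(set(keys))


class TestSplit:
    def test_ten_pairs_split_seven_three(self):
        samples = make_class_samples((3, 3), shape=SHAPE)  # 6 same + 6 diff
        ps = build_pairs(samples, seed=0)
        tr, val = split_train_val(ps, seed=0)
        assert len(tr) == round(0.7 * 12) and len(tr) + len(val) == 12
        tr_same = sum(p.pair_label for p in tr)
        assert 3 <= tr_same <= 5

    def test_same_seed_identical(self):
        samples = make_class_samples((4, 4), shape=SHAPE)
        ps = build_pairs(samples, seed=0)
        t1, v1 = split_train_val(ps, seed=9)
        t2, v2 = split_train_val(ps, seed=9)
        assert [p.key for p in t1] == [p.key for p in t2]
        assert [p.key for p in v1] == [p.key for p in v2]

    def test_exact_stratification_when_divisible(self):
        """50 same + 50 dissimilar pairs split exactly 35/15 per label."""
        samples = make_class_samples((10, 10), shape=(4, 4, 3))  # S=90, Z=1
        ps = build_pairs(samples, seed=0)
        # trim to exactly 50/50 preserving the PairSet structure
        same = [p for p in ps.pairs if p.pair_label == 1][:50]
        diff = [p for p in ps.pairs if p.pair_label == 0][:50]
        from pmfesn.pairs import PairSet

        trimmed = PairSet(pairs=same + diff, n_same=50, n_dissimilar=50, allocation={(0, 1): 50})
        tr, val = split_train_val(trimmed, seed=1)
        assert sum(p.pair_label for p in tr) == 35
        assert sum(1 - p.pair_label for p in tr) == 35
        assert sum(p.pair_label for p in val) == 15
        assert sum(1 - p.pair_label for p in val) == 15

    def test_disjoint_cover(self):
        samples = make_class_samples((3, 3, 3), shape=SHAPE)
        ps = build_pairs(samples, seed=0)
        tr, val = split_train_val(ps, seed=0)
        all_keys = sorted((min(p.key), max(p.key)) for p in ps.pairs)
        got = sorted((min(p.key), max(p.key)) for p in tr + val)
        assert got == all_keys
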
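"""ROC cut-offs, complexity-class re-stratification, aggressiveness tiers."""

import numpy as np
import pytest

from fractopath.errors import LabelError
from fractopath.stratification import (
    PAPER_D0_CUTOFFS,
    ClassBoundaries,
    aggressiveness,
    classify_d0,
    paper_boundaries,
    restratify,
    roc,
)


class TestRoc:
    def test_perfect_separation_midpoint_cutoff(self):
        r = roc([1, 2, 3, 4, 5, 6], [0, 0, 0, 1, 1, 1])
        assert r.auc == 1.0
        assert r.optimal_cutoff == 3.5
        # 3-vs-3 rank-sum floor is p = 0.1; significance needs larger groups
        assert r.p_value <= 0.1
        big = roc(list(range(40)), [0] * 20 + [1] * 20)
        assert big.p_value < 0.001

    def test_identical_distributions_auc_half(self):
        scores = [1, 2, 3, 4, 1, 2, 3, 4]
        labels = [0, 0, 0, 0, 1, 1, 1, 1]
        assert roc(scores, labels).auc == 0.5

    def test_auc_equals_pairwise_concordance(self, rng):
        scores = rng.normal(size=8).round(1)  # rounding forces some ties
        labels = np.array([0, 1, 0, 1, 1, 0, 0, 1])
        r = roc(scores, labels)
        pos = scores[labels == 1]
        neg = scores[labels == 0]
        conc = sum(
            1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg
        )
        assert r.auc == pytest.approx(conc / (pos.size * neg.size))

    def test_complementary_labels_sum_to_one(self, rng):
        scores = rng.normal(size=30)
        labels = rng.random(30) < 0.4
        if labels.all() or not labels.any():
            labels[:2] = [True, False]
        assert roc(scores, labels).auc + roc(scores, ~labels).auc == pytest.approx(
            1.0
        )

    def test_curve_is_monotone(self, rng):
        scores = rng.normal(size=50)
        labels = rng.random(50) < 0.5
        labels[:2] = [True, False]
        r = roc(scores, labels)
        # thresholds ascend => sensitivity falls, specificity rises
        assert np.all(np.diff(r.sensitivity) <= 0)
        assert np.all(np.diff(r.specificity) >= 0)

    def test_one_class_input(self):
        with pytest.raises(LabelError):
            roc([1.0, 2.0], [1, 1])


class TestRestratify:
    def test_interval_consistent_is_fixed_point(self):
        values = np.array([1.0, 1.1, 1.2, 2.0, 2.1, 2.2])
        labels = np.array(["C1"] * 3 + ["C2"] * 3)
        res = restratify(values, labels)
        assert res.n_reassigned == 0
        assert np.array_equal(res.assignments, labels)
        assert res.boundaries.cutoffs == (
            roc(values, labels == "C2").optimal_cutoff,
        )

    def test_hand_traced_twelve_case_fixture(self):
        # one C1-labeled case (1.60) sits above every other C1 value and
        # above the C1/C2 gap; it must move to C2 and the result must be
        # interval-consistent with all adjacent AUCs 1.0
        values = np.array(
            [1.50, 1.51, 1.52, 1.60, 1.56, 1.57, 1.58, 1.59, 1.62, 1.63, 1.64, 1.65]
        )
        labels = np.array(["C1"] * 4 + ["C2"] * 4 + ["C3"] * 4)
        res = restratify(values, labels)
        assert res.assignments[3] == "C2"
        assert res.n_reassigned >= 1
        for lo, hi in (("C1", "C2"), ("C2", "C3")):
            mask = np.isin(res.assignments, [lo, hi])
            r = roc(values[mask], res.assignments[mask] == hi)
            assert r.auc == 1.0
            assert r.sensitivity.max() == 1.0 and r.specificity.max() == 1.0

    def test_idempotent_under_reapplication(self, rng):
        values = rng.normal(1.6, 0.1, size=60)
        labels = np.array(["C%d" % (1 + i % 3) for i in range(60)])
        first = restratify(values, labels)
        second = restratify(values, first.assignments)
        assert second.n_reassigned == 0
        assert np.array_equal(first.assignments, second.assignments)

    def test_classify_reproduces_assignments(self, rng):
        values = rng.normal(1.6, 0.08, size=80)
        labels = np.where(values < 1.6, "C1", "C2")
        # scramble a fifth of the labels, then restratify
        idx = rng.choice(80, size=16, replace=False)
        labels[idx] = np.where(labels[idx] == "C1", "C2", "C1")
        res = restratify(values, labels)
        assert np.array_equal(
            classify_d0(values, res.boundaries), res.assignments
        )

    def test_pathological_overlap_converges_to_intervals(self):
        # the lone C2 value sits above every C3 value; the fixed point must
        # still be interval-consistent (classes exchange members as needed)
        values = np.array([1.0, 1.1, 3.0, 2.0, 2.1, 2.2])
        labels = np.array(["C1", "C1", "C2", "C3", "C3", "C3"])
        res = restratify(values, labels)
        assert np.array_equal(
            classify_d0(values, res.boundaries), res.assignments
        )
        for name in res.boundaries.class_names:
            assert (res.assignments == name).any()
        # every surviving class keeps members: one-step symmetric moves let
        # neighbors absorb a stray class rather than empty it
        assert res.collapsed_classes == ()

    def test_single_group_rejected(self):
        with pytest.raises(LabelError):
            restratify([1.0, 2.0], ["C1", "C1"])


class TestClassifyD0:
    @pytest.mark.parametrize(
        "value, expected",
        [
            (1.50, "C1"),
            (1.5450, "C1"),  # boundary goes to the lower class
            (1.5451, "C2"),
            (1.7986, "C7"),  # reference C7 mean
            (1.60, "C3"),
        ],
    )
    def test_paper_boundaries(self, value, expected):
        assert classify_d0(value) == expected

    def test_vectorized(self):
        out = classify_d0(np.array([1.50, 1.60, 1.80]))
        assert out.tolist() == ["C1", "C3", "C7"]

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            classify_d0(float("nan"))

    def test_boundaries_must_increase(self):
        with pytest.raises(ValueError):
            ClassBoundaries(classifier="d0", cutoffs=(1.6, 1.5))

    def test_shipped_cutoffs(self):
        b = paper_boundaries()
        assert b.cutoffs == PAPER_D0_CUTOFFS
        assert b.provenance == "fixed"
        assert b.class_names == ("C1", "C2", "C3", "C4", "C5", "C6", "C7")


class TestAggressiveness:
    @pytest.mark.parametrize(
        "fv, expected",
        [
            (dict(d0=1.55, lfd_mean=1.25, lcfd_mean=1.60, h=0.65, lam=0.85), "low"),
            (dict(d0=1.75, lfd_mean=1.80, lcfd_mean=1.72, h=0.95, lam=0.62), "high"),
            (
                dict(d0=1.63, lfd_mean=1.55, lcfd_mean=1.60, h=0.80, lam=0.75),
                "intermediate",
            ),
            # four of five low criteria met -> still intermediate
            (
                dict(d0=1.55, lfd_mean=1.25, lcfd_mean=1.60, h=0.65, lam=0.75),
                "intermediate",
            ),
        ],
    )
    def test_tier_assignment(self, fv, expected):
        assert aggressiveness(fv) == expected

    def test_missing_measure(self):
        with pytest.raises(ValueError):
            aggressiveness(dict(d0=1.5, lfd_mean=1.2, lcfd_mean=1.6, h=0.6))

    def test_non_finite_measure(self):
        with pytest.raises(ValueError):
            aggressiveness(
                dict(d0=float("nan"), lfd_mean=1.2, lcfd_mean=1.6, h=0.6, lam=0.9)
            )
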
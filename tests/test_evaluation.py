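"""Pseudo-absences, AUC, Kappa/TSS maximization, performance bins,
and the replicate harness."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from maxenm import (
    ConfusionCounts,
    bootstrap_evaluate,
    build_features,
    confusion_metrics,
    generate_pseudo_absences,
    maximize_threshold,
    performance_class,
    rank_auc,
    sample_background,
)
from maxenm.maxent import merge_presences_into_background
from maxenm.occurrences import OccurrenceRecord, OccurrenceSet


def brute_force_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRankAuc:
    def test_four_pair_example(self):
        assert rank_auc([0.8, 0.6], [0.7, 0.2]) == pytest.approx(0.75)

    def test_all_ties_half(self):
        assert rank_auc([0.5] * 3, [0.5] * 4) == pytest.approx(0.5)

    def test_perfect_separation(self):
        assert rank_auc([0.9, 0.8], [0.1, 0.2]) == 1.0

    def test_agrees_with_brute_force_on_random_sets(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            pos = rng.choice(np.linspace(0, 1, 21), size=rng.integers(1, 15))
            neg = rng.choice(np.linspace(0, 1, 21), size=rng.integers(1, 15))
            assert rank_auc(pos, neg) == pytest.approx(brute_force_auc(pos, neg))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(1)
        pos, neg = rng.uniform(size=20), rng.uniform(size=30)
        a = rank_auc(pos, neg)
        for f in (np.exp, np.tanh, lambda x: x**3 + x):
            assert rank_auc(f(pos), f(neg)) == pytest.approx(a)

    def test_empty_side_rejected(self):
        with pytest.raises(ValueError):
            rank_auc([], [0.5])


class TestConfusionMetrics:
    def test_printed_counts(self):
        m = confusion_metrics(ConfusionCounts(tp=45, fn=5, tn=180, fp=20))
        assert m["sensitivity"] == pytest.approx(0.9)
        assert m["specificity"] == pytest.approx(0.9)
        assert m["tss"] == pytest.approx(0.8)
        # independent Cohen's kappa: Po=0.9, Pe=(65*50+185*200)/250^2=0.644
        assert m["kappa"] == pytest.approx((0.9 - 0.644) / (1 - 0.644), abs=1e-4)
        assert m["kappa"] == pytest.approx(0.7191, abs=1e-4)

    def test_perfect_classifier(self):
        m = confusion_metrics(ConfusionCounts(tp=10, fn=0, tn=20, fp=0))
        assert m["tss"] == 1.0 and m["kappa"] == 1.0

    def test_empty_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_metrics(ConfusionCounts(tp=0, fn=0, tn=5, fp=5))


class TestMaximizeThreshold:
    def test_separable_scores_smallest_maximizer(self):
        thr, val = maximize_threshold([0.9, 0.8], [0.1, 0.2], "tss")
        assert val == 1.0
        assert thr == pytest.approx(0.201)

    def test_all_equal_scores_zero_tss(self):
        _, val = maximize_threshold([0.4] * 5, [0.4] * 5, "tss")
        assert val == 0.0

    def test_agrees_with_unique_score_scan(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            pos = rng.uniform(size=rng.integers(2, 20))
            neg = rng.uniform(size=rng.integers(2, 20))
            for metric in ("tss", "kappa"):
                _, val = maximize_threshold(pos, neg, metric)
                # oracle: evaluate at every unique score (each achievable split)
                best = -np.inf
                for t in np.concatenate([[0.0], np.unique(np.concatenate([pos, neg]))]):
                    tp = (pos >= t).sum()
                    fp = (neg >= t).sum()
                    c = ConfusionCounts(tp=tp, fn=len(pos) - tp, tn=len(neg) - fp, fp=fp)
                    best = max(best, confusion_metrics(c)[metric])
                assert val == pytest.approx(best, abs=0.05)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        pos=st.lists(st.floats(0, 1), min_size=1, max_size=10),
        neg=st.lists(st.floats(0, 1), min_size=1, max_size=10),
    )
    def test_tss_and_kappa_values_bounded(self, pos, neg):
        for metric in ("tss", "kappa"):
            thr, val = maximize_threshold(pos, neg, metric)
            assert 0.0 <= thr <= 1.0
            assert -1.0 <= val <= 1.0

    def test_random_classifier_tss_centered_on_zero(self):
        # TSS of a random classifier at a fixed threshold: zero mean over
        # permuted label assignments (maximized TSS is biased upward)
        rng = np.random.default_rng(3)
        scores = rng.uniform(size=60)
        fixed = []
        for _ in range(1000):
            lab = rng.permutation(60) < 20
            tp = (scores[lab] >= 0.5).sum()
            fp = (scores[~lab] >= 0.5).sum()
            fixed.append(tp / 20 + (40 - fp) / 40 - 1)
        assert abs(np.mean(fixed)) < 0.02

    def test_tss_and_kappa_share_sign(self):
        rng = np.random.default_rng(4)
        for _ in range(50):
            c = ConfusionCounts(*rng.integers(1, 50, size=4))
            m = confusion_metrics(c)
            assert np.sign(np.round(m["tss"], 12)) == np.sign(np.round(m["kappa"], 12))


class TestPerformanceClass:
    @pytest.mark.parametrize(
        "stat,value,label",
        [
            ("auc", 0.966, "excellent"),
            ("auc", 0.85, "good"),
            ("auc", 0.75, "fair"),
            ("auc", 0.65, "poor"),
            ("auc", 0.55, "failed"),
            ("auc", 0.9, "excellent"),  # boundary goes up
            ("kappa", 0.813, "excellent"),
            ("kappa", 0.5, "good"),
            ("kappa", 0.2, "poor"),
            ("tss", 0.882, "good to excellent"),
            ("tss", 0.6, "useful"),
            ("tss", 0.3, "poor"),
        ],
    )
    def test_bins(self, stat, value, label):
        assert performance_class(stat, value) == label

    def test_unknown_statistic_rejected(self):
        with pytest.raises(ValueError):
            performance_class("f1", 0.5)


class TestPseudoAbsences:
    def test_min_distance_to_presences(self, small_dataset, small_thinned):
        pa = generate_pseudo_absences(
            small_dataset.stack, small_thinned, n=200, exclusion_radius=1000.0, seed=0
        )
        assert pa.shape == (200, 2)
        xy = small_thinned.xy
        d = np.sqrt(((pa[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
        assert d.min() >= 1000.0

    def test_no_presences_no_exclusion(self, small_dataset):
        empty = OccurrenceSet(records=[])
        pa = generate_pseudo_absences(small_dataset.stack, empty, n=50, seed=1)
        assert pa.shape == (50, 2)

    def test_everything_excluded_rejected(self, constant_stack):
        presences = OccurrenceSet(records=[OccurrenceRecord(id="c", x=1250.0, y=1000.0)])
        with pytest.raises(ValueError):
            generate_pseudo_absences(constant_stack, presences, n=5, exclusion_radius=1e6, seed=0)

    def test_reproducible_by_seed(self, small_dataset, small_thinned):
        a = generate_pseudo_absences(small_dataset.stack, small_thinned, n=100, seed=4)
        b = generate_pseudo_absences(small_dataset.stack, small_thinned, n=100, seed=4)
        np.testing.assert_array_equal(a, b)


@pytest.fixture(scope="module")
def harness(small_dataset):
    stack = small_dataset.stack
    occ = small_dataset.occurrences  # one record per cell already
    xy = occ.xy
    r, c = stack.spec.index_of(xy[:, 0], xy[:, 1])
    bg = sample_background(stack, n=1500, seed=5)
    bg = merge_presences_into_background(bg, r, c, stack)
    exp = build_features(
        bg.table,
        {l.name: l.kind for l in stack.layers},
        n_presences=len(occ),
        hinge_knots=10,
    )
    pa = generate_pseudo_absences(stack, occ, n=100, exclusion_radius=500.0, seed=5)
    return stack, occ, pa, bg, exp


class TestBootstrapEvaluate:

    def test_replicate_counts_and_split_sizes(self, harness):
        stack, occ, pa, bg, exp = harness
        summary = bootstrap_evaluate(
            stack, ["clim_a", "clim_b"], occ, pa, bg, exp, reps=5, seed=6
        )
        assert len(summary.replicates) == 5
        n = len(occ)
        n_train = int(round(0.75 * n))
        for rep in summary.replicates:
            assert len(rep.train_ids) == n_train
            assert len(rep.test_ids) == n - n_train
            assert set(rep.train_ids).isdisjoint(rep.test_ids)

    def test_paper_sample_size_split_arithmetic(self):
        # 64 presences at 75/25 -> 48 train / 16 test
        assert int(round(0.75 * 64)) == 48 and 64 - 48 == 16

    def test_summary_means_match_replicates(self, harness):
        stack, occ, pa, bg, exp = harness
        summary = bootstrap_evaluate(
            stack, ["clim_a", "clim_b"], occ, pa, bg, exp, reps=4, seed=7
        )
        assert summary.mean_test_auc == np.mean([r.test_auc for r in summary.replicates])
        assert summary.mean_max_tss == np.mean([r.max_tss for r in summary.replicates])
        assert summary.mean_tss_threshold == np.mean(
            [r.tss_threshold for r in summary.replicates]
        )

    def test_structured_truth_recovers_high_auc(self, harness):
        stack, occ, pa, bg, exp = harness
        summary = bootstrap_evaluate(
            stack, ["clim_a", "clim_b"], occ, pa, bg, exp, reps=5, seed=8
        )
        assert summary.mean_test_auc >= 0.85

    def test_too_few_presences_rejected(self, harness):
        stack, occ, pa, bg, exp = harness
        tiny = OccurrenceSet(records=occ.records[:3])
        with pytest.raises(ValueError):
            bootstrap_evaluate(stack, ["clim_a"], tiny, pa, bg, exp, reps=2, seed=0)
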
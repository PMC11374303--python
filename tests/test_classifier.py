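"""Enrichment score, 1-D logistic anchor classifier, ROC, FPR threshold."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import roc_auc_score

from proxiscore import (AnchorSets, ClassifierFit, call_enriched,
                        call_enriched_by_cutoff, compute_enrichment_scores,
                        crossvalidate, fit_enrichment_classifier,
                        fit_logistic_1d, roc_auc, run_differential,
                        select_fpr_threshold)
from proxiscore.diffabund import ContrastResult


def contrast_from(mlr, q):
    tab = pd.DataFrame({
        "mean_log2_ratio": mlr, "p_value": q, "q_value": q,
        "n_pairs": 4, "degenerate": False,
    }, index=[f"p{i}" for i in range(len(mlr))])
    return ContrastResult(tab)


def series(values, prefix="p"):
    return pd.Series(np.asarray(values, float),
                     index=[f"{prefix}{i}" for i in range(len(values))])


class TestEnrichmentScore:
    @pytest.mark.parametrize("mlr,q,expected", [
        (2.0, 0.01, 4.0),     # 2 * -log10(0.01)
        (3.0, 1.0, 0.0),      # q=1 kills any ratio
        (-1.0, 0.1, -1.0),    # sign follows the ratio
    ])
    def test_score_arithmetic(self, mlr, q, expected):
        st = compute_enrichment_scores(contrast_from([mlr], [q]))
        assert st.scores.iloc[0] == pytest.approx(expected, abs=1e-12)

    def test_missing_rows_dropped_and_counted(self):
        res = contrast_from([1.0, np.nan, 2.0], [0.1, 0.1, np.nan])
        st = compute_enrichment_scores(res)
        assert len(st.scores) == 1 and st.n_dropped == 2

    def test_zero_q_clamped_finite_and_strictest(self):
        st = compute_enrichment_scores(contrast_from([1.0, 1.0], [0.0, 1e-8]))
        assert st.meta["q_zero_clamp"] == np.finfo(float).tiny
        assert np.isfinite(st.scores).all()
        # the q = 0 protein stays strictly most significant
        assert st.scores.iloc[0] > st.scores.iloc[1]


class TestLogistic1D:
    def test_symmetric_classes_cross_at_zero(self):
        s = series([-1.0] * 20 + [1.0] * 20)
        anchors = AnchorSets(set(s.index[20:]), set(s.index[:20]))
        a, b = fit_logistic_1d(s, anchors)
        assert a == pytest.approx(0.0, abs=1e-3)
        assert b > 0

    def test_score_scaling_scales_slope_inversely(self):
        rng = np.random.default_rng(0)
        s = series(np.concatenate([rng.normal(-1, 0.8, 50),
                                   rng.normal(1, 0.8, 50)]))
        anchors = AnchorSets(set(s.index[50:]), set(s.index[:50]))
        _, b1 = fit_logistic_1d(s, anchors)
        _, b3 = fit_logistic_1d(s * 3.0, anchors)
        assert b3 == pytest.approx(b1 / 3.0, rel=1e-3)

    def test_label_swap_flips_slope_sign(self):
        rng = np.random.default_rng(1)
        s = series(np.concatenate([rng.normal(-1, 1, 30), rng.normal(1, 1, 30)]))
        a = AnchorSets(set(s.index[30:]), set(s.index[:30]))
        swapped = AnchorSets(a.negatives, a.positives)
        _, b = fit_logistic_1d(s, a)
        _, b_swap = fit_logistic_1d(s, swapped)
        assert b_swap == pytest.approx(-b, rel=1e-6)

    def test_empty_class_after_intersection_errors(self):
        s = series([1.0, 2.0])
        with pytest.raises(ValueError, match="empty"):
            fit_logistic_1d(s, AnchorSets({"p0"}, {"absent"}))

    def test_overlapping_anchor_sets_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            AnchorSets({"a", "b"}, {"b", "c"})


def brute_force_auc(pos, neg):
    wins = sum(1.0 if p > n else 0.5 if p == n else 0.0
               for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestRocAuc:
    def test_worked_example(self):
        _, auc = roc_auc([2, 3], [1, 2])
        assert auc == pytest.approx(0.875)

    def test_disjoint_supports(self):
        _, auc = roc_auc([10, 11], [1, 2, 3])
        assert auc == 1.0

    def test_all_tied(self):
        _, auc = roc_auc([5.0], [5.0])
        assert auc == 0.5

    def test_matches_exhaustive_pair_counting(self):
        rng = np.random.default_rng(2)
        for _ in range(500):
            n_pos = int(rng.integers(1, 13))
            n_neg = int(rng.integers(1, 13))
            pos = rng.integers(0, 6, n_pos).astype(float)  # force ties
            neg = rng.integers(0, 6, n_neg).astype(float)
            _, auc = roc_auc(pos, neg)
            assert auc == pytest.approx(brute_force_auc(pos, neg), abs=1e-12)

    def test_matches_sklearn(self):
        rng = np.random.default_rng(3)
        pos, neg = rng.normal(1, 1, 40), rng.normal(0, 1, 60)
        _, auc = roc_auc(pos, neg)
        ref = roc_auc_score([1] * 40 + [0] * 60, np.concatenate([pos, neg]))
        assert auc == pytest.approx(ref, abs=1e-12)

    def test_roc_points_span_the_unit_square(self):
        rng = np.random.default_rng(4)
        roc, _ = roc_auc(rng.normal(1, 1, 20), rng.normal(0, 1, 20))
        assert roc.iloc[0][["fpr", "tpr"]].tolist() == [0.0, 0.0]
        assert roc.iloc[-1][["fpr", "tpr"]].tolist() == [1.0, 1.0]
        assert (np.diff(roc["fpr"]) >= 0).all()


class TestCrossValidation:
    def test_perfect_separation_gives_auc_one(self):
        s = series(list(range(40)) + list(range(100, 140)))
        anchors = AnchorSets(set(s.index[40:]), set(s.index[:40]))
        cv = crossvalidate(s, anchors, n_folds=10, n_repeats=2, seed=0)
        assert cv.mean_auc == 1.0

    def test_identical_distributions_give_half(self):
        rng = np.random.default_rng(5)
        s = series(rng.normal(0, 1, 300))
        anchors = AnchorSets(set(s.index[:150]), set(s.index[150:]))
        cv = crossvalidate(s, anchors, n_folds=10, n_repeats=5, seed=1)
        assert abs(cv.mean_auc - 0.5) < 3 * cv.sd_auc

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(6)
        s = series(np.concatenate([rng.normal(0, 1, 50), rng.normal(2, 1, 50)]))
        anchors = AnchorSets(set(s.index[50:]), set(s.index[:50]))
        cv1 = crossvalidate(s, anchors, n_repeats=3, seed=42)
        cv2 = crossvalidate(s, anchors, n_repeats=3, seed=42)
        assert np.array_equal(cv1.fold_aucs, cv2.fold_aucs)

    def test_class_smaller_than_folds_errors(self):
        s = series(range(15))
        anchors = AnchorSets(set(s.index[:5]), set(s.index[5:]))
        with pytest.raises(ValueError, match="fewer folds"):
            crossvalidate(s, anchors, n_folds=10)


class TestFprThreshold:
    def test_brute_force_on_distinct_negatives(self):
        s = series(np.arange(1.0, 101.0), prefix="n")
        pos = series([200.0, 201.0], prefix="x")
        scores = pd.concat([s, pos])
        anchors = AnchorSets(set(pos.index), set(s.index))
        t, fpr = select_fpr_threshold(scores, anchors, target_fpr=0.05)
        assert t == 96.0 and fpr == 0.05

    def test_target_zero_calls_nothing_on_negatives(self):
        s = series(np.arange(10.0), prefix="n")
        pos = series([20.0], prefix="x")
        scores = pd.concat([s, pos])
        anchors = AnchorSets(set(pos.index), set(s.index))
        t, fpr = select_fpr_threshold(scores, anchors, target_fpr=0.0)
        assert fpr == 0.0 and t > 9.0

    def test_all_tied_negatives_pick_zero_side(self):
        s = series([5.0] * 10, prefix="n")
        pos = series([5.0], prefix="x")
        scores = pd.concat([s, pos])
        anchors = AnchorSets(set(pos.index), set(s.index))
        t, fpr = select_fpr_threshold(scores, anchors, target_fpr=0.05)
        assert fpr == 0.0 and t == np.inf

    def test_lower_target_never_lowers_threshold(self):
        rng = np.random.default_rng(8)
        s = series(rng.normal(0, 1, 200), prefix="n")
        pos = series(rng.normal(3, 1, 50), prefix="x")
        scores = pd.concat([s, pos])
        anchors = AnchorSets(set(pos.index), set(s.index))
        thresholds = [select_fpr_threshold(scores, anchors, t)[0]
                      for t in (0.2, 0.1, 0.05, 0.01, 0.0)]
        assert all(b >= a for a, b in zip(thresholds, thresholds[1:]))


class TestCalls:
    def test_boundary_score_is_enriched(self):
        s = series([1.0, 2.0, 3.0])
        fit = ClassifierFit(0.0, 1.0, threshold=2.0, achieved_fpr=0.05,
                            target_fpr=0.05)
        calls = call_enriched(s, fit)
        assert calls["enriched"].tolist() == [False, True, True]

    def test_infinite_threshold_zero_calls(self):
        s = series([1.0, 1e9])
        fit = ClassifierFit(0.0, 1.0, threshold=np.inf, achieved_fpr=0.0,
                            target_fpr=0.0)
        assert call_enriched(s, fit)["enriched"].sum() == 0

    def test_monotone_transform_invariance_after_rethreshold(self):
        rng = np.random.default_rng(9)
        s = series(np.concatenate([rng.normal(0, 1, 100),
                                   rng.normal(4, 1, 30)]))
        anchors = AnchorSets(set(s.index[100:]), set(s.index[:100]))
        t1, _ = select_fpr_threshold(s, anchors, 0.05)
        transformed = pd.Series(np.exp(s / 3.0), index=s.index)
        t2, _ = select_fpr_threshold(transformed, anchors, 0.05)
        calls1 = s >= t1
        calls2 = transformed >= t2
        assert calls1.equals(calls2)

    def test_noise_free_end_to_end_recovers_truth(self):
        # planted interactors stronger than the anchor positives, so the
        # anchor-derived threshold always lies below every interactor score
        from proxiscore import BioidSimConfig, generate_bioid_dataset
        config = BioidSimConfig(n_background=300, n_anchor_pos=20,
                                n_anchor_neg=40, n_planted_interactors=10,
                                effect_log2=5.0, anchor_effect_log2=4.0,
                                rep_noise_sd=0.0, pair_offset_sd=0.0, seed=5)
        table, design, truth = generate_bioid_dataset(config)
        res = run_differential(table, design, "main", normalize=False)
        scores = compute_enrichment_scores(res)
        anchors = AnchorSets(set(truth.proteins_with_label("anchor_pos")),
                             set(truth.proteins_with_label("anchor_neg")))
        fit = fit_enrichment_classifier(scores, anchors, n_repeats=2, seed=0)
        calls = call_enriched(scores, fit, truth.labels)
        enriched = set(calls.index[calls["enriched"]])
        non_anchor = enriched - anchors.positives - anchors.negatives
        assert non_anchor == set(truth.proteins_with_label("planted_interactor"))
        assert fit.achieved_fpr == 0.0

    @pytest.mark.parametrize("mlr,q,expected", [
        (1.0, 0.01, False),   # boundary: strict >
        (2.0, 0.04, True),
        (2.0, 0.05, False),   # boundary: strict <
    ])
    def test_cutoff_calls_use_strict_inequalities(self, mlr, q, expected):
        calls = call_enriched_by_cutoff(contrast_from([mlr], [q]))
        assert bool(calls["enriched"].iloc[0]) is expected
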
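"""Evaluation metric panel: formulas, edge cases, independent oracles."""

import math

import numpy as np
import pytest
from sklearn.metrics import cohen_kappa_score, roc_auc_score

from tasteforest import ConfusionCounts, confusion, evaluate, panel, roc_auc
from tasteforest.metrics import dual_report


class TestConfusion:
    def test_perfect_classifier(self):
        labels = ["sweet"] * 5 + ["bitter"] * 5
        c = confusion(labels, labels, "sweet")
        assert (c.tp, c.tn, c.fp, c.fn) == (5, 5, 0, 0)

    def test_degenerate_all_positive_predictor(self):
        labels = ["sweet"] * 3 + ["bitter"] * 7
        preds = ["sweet"] * 10
        c = confusion(labels, preds, "sweet")
        assert (c.tp, c.tn, c.fp, c.fn) == (3, 0, 7, 0)

    def test_swapping_positive_class_swaps_cells(self):
        rng = np.random.default_rng(5)
        labels = ["sweet" if x else "bitter" for x in rng.integers(0, 2, 50)]
        preds = ["sweet" if x else "bitter" for x in rng.integers(0, 2, 50)]
        cs = confusion(labels, preds, "sweet")
        cb = confusion(labels, preds, "bitter")
        assert (cs.tp, cs.tn, cs.fp, cs.fn) == (cb.tn, cb.tp, cb.fn, cb.fp)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            confusion(["sweet"], [], "sweet")

    def test_unknown_token_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            confusion(["salty"], ["sweet"], "sweet")


class TestPanel:
    def test_hand_computed_example(self):
        r = panel(ConfusionCounts(tp=9, tn=9, fp=1, fn=1, positive_class="sweet"))
        assert r.accuracy == pytest.approx(0.9)
        assert r.sensitivity == pytest.approx(0.9)
        assert r.specificity == pytest.approx(0.9)
        assert r.precision == pytest.approx(0.9)
        assert r.ner == pytest.approx(0.9)
        # p_o = 0.9, p_e = 0.5 (symmetric marginals) => kappa = 0.8
        assert r.cohens_kappa == pytest.approx(0.8)

    def test_perfect_counts_give_all_ones(self):
        r = panel(ConfusionCounts(tp=4, tn=6, fp=0, fn=0, positive_class="sweet"))
        for v in (r.accuracy, r.sensitivity, r.specificity, r.precision,
                  r.f_measure, r.ner, r.cohens_kappa):
            assert v == pytest.approx(1.0)

    def test_zero_denominators_are_nan_not_zero(self):
        # no predicted positives: precision undefined
        r = panel(ConfusionCounts(tp=0, tn=8, fp=0, fn=2, positive_class="sweet"))
        assert math.isnan(r.precision)
        assert math.isnan(r.f_measure)
        assert r.specificity == 1.0

    def test_kappa_matches_sklearn_on_random_vectors(self):
        rng = np.random.default_rng(17)
        for _ in range(50):
            n = int(rng.integers(10, 80))
            labels = ["sweet" if x else "bitter" for x in rng.integers(0, 2, n)]
            preds = ["sweet" if x else "bitter" for x in rng.integers(0, 2, n)]
            r = panel(confusion(labels, preds, "sweet"))
            expected = cohen_kappa_score(labels, preds)
            if math.isnan(r.cohens_kappa):
                continue  # one-class marginals: sklearn coerces to 0 or nan
            assert r.cohens_kappa == pytest.approx(expected, abs=1e-12)

    def test_chance_level_kappa_near_zero(self):
        # predictions independent of labels with matched marginals
        rng = np.random.default_rng(3)
        kappas = []
        for _ in range(2000):
            labels = ["sweet" if x else "bitter" for x in rng.integers(0, 2, 40)]
            preds = list(labels)
            rng.shuffle(preds)
            k = panel(confusion(labels, preds, "sweet")).cohens_kappa
            if not math.isnan(k):
                kappas.append(k)
        assert abs(np.mean(kappas)) < 0.02

    def test_kappa_never_exceeds_accuracy(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = int(rng.integers(8, 60))
            labels = ["sweet" if x else "bitter" for x in rng.integers(0, 2, n)]
            preds = ["sweet" if x else "bitter" for x in rng.integers(0, 2, n)]
            r = panel(confusion(labels, preds, "sweet"))
            if not math.isnan(r.cohens_kappa):
                assert r.cohens_kappa <= r.accuracy + 1e-12


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = ["sweet", "sweet", "bitter", "bitter"]
        assert roc_auc(labels, [0.9, 0.8, 0.3, 0.1], "sweet") == 1.0

    def test_constant_scores_give_half(self):
        labels = ["sweet", "sweet", "bitter", "bitter"]
        assert roc_auc(labels, [0.5] * 4, "sweet") == 0.5

    def test_enumerated_pairs(self):
        labels = ["sweet", "sweet", "bitter", "bitter"]
        assert roc_auc(labels, [0.9, 0.4, 0.6, 0.1], "sweet") == 0.75

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="positive and one negative"):
            roc_auc(["sweet", "sweet"], [0.4, 0.2], "sweet")

    def test_rank_formula_equals_trapezoidal(self):
        rng = np.random.default_rng(21)
        for _ in range(500):
            n = int(rng.integers(4, 60))
            labels = (["sweet", "bitter"] +
                      ["sweet" if x else "bitter" for x in rng.integers(0, 2, n)])
            # discretized scores force ties
            scores = np.round(rng.random(len(labels)), 1)
            ours = roc_auc(labels, scores, "sweet")
            ref = roc_auc_score([y == "sweet" for y in labels], scores)
            assert ours == pytest.approx(ref, abs=1e-12)


class TestEvaluate:
    def test_all_ones_for_perfect_input(self):
        labels = ["sweet"] * 3 + ["bitter"] * 4
        scores = [0.9, 0.8, 0.95, 0.2, 0.1, 0.3, 0.05]
        r = evaluate(labels, labels, scores, "sweet")
        assert r.accuracy == r.roc_auc == r.f_measure == 1.0

    def test_dual_perspectives_mirror(self):
        rng = np.random.default_rng(31)
        labels = ["sweet" if x else "bitter" for x in rng.integers(0, 2, 60)]
        sweet_scores = rng.random(60)
        preds = ["sweet" if s >= 0.5 else "bitter" for s in sweet_scores]
        reports = dual_report(labels, preds, sweet_scores)
        assert reports["sweet"].sensitivity == pytest.approx(
            reports["bitter"].specificity)
        assert reports["sweet"].specificity == pytest.approx(
            reports["bitter"].sensitivity)
        assert reports["sweet"].accuracy == pytest.approx(
            reports["bitter"].accuracy)

    def test_random_scores_auc_near_half(self):
        rng = np.random.default_rng(41)
        labels = ["sweet" if x else "bitter" for x in rng.integers(0, 2, 200)]
        scores = rng.random(200)
        preds = ["sweet" if s >= 0.5 else "bitter" for s in scores]
        r = evaluate(labels, preds, scores, "sweet")
        assert abs(r.roc_auc - 0.5) < 0.1
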
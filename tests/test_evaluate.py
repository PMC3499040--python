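"""Classifier scoring, fixed-precision thresholding, ROC/PR metrics."""

import numpy as np
import pandas as pd
import pytest

from zincsite.evaluate import (ConfusionCounts, ZincSiteClassifier,
                               aurpc_davis_goadrich, confusion_metrics,
                               counts_at_threshold, evaluate_residue_level,
                               protein_level, roc_auc, threshold_at_precision)


class TestConfusionMetrics:
    def test_formulas(self):
        m = confusion_metrics(ConfusionCounts(tp=8, fp=2, tn=85, fn=5))
        assert m["REC"] == pytest.approx(8 / 13)
        assert m["PRE"] == pytest.approx(0.8)
        assert m["SPE"] == pytest.approx(85 / 87)
        assert m["FPR"] == pytest.approx(2 / 87)

    def test_zero_denominators_flagged(self):
        m = confusion_metrics(ConfusionCounts(tp=0, fp=0, tn=5, fn=0))
        assert m["PRE"] == 0.0 and m["REC"] == 0.0
        assert m["degenerate"]

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionCounts(tp=-1, fp=0, tn=0, fn=0)

    def test_integer_identity(self):
        c = ConfusionCounts(tp=17, fp=3, tn=50, fn=13)
        m = confusion_metrics(c)
        assert round(m["REC"] * (c.tp + c.fn)) == c.tp


class TestThresholdAtPrecision:
    def test_separable(self):
        y = np.array([1, 1, -1])
        s = np.array([0.9, 0.8, 0.1])
        t, achieved = threshold_at_precision(y, s, 0.75)
        assert achieved
        c = counts_at_threshold(y, s, t)
        assert (c.tp, c.fp) == (2, 0)

    def test_unachievable_flag(self):
        y = np.array([1, -1, -1])
        s = np.array([0.1, 0.8, 0.9])
        _, achieved = threshold_at_precision(y, s, 0.75)
        assert not achieved

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        n = 30
        y = np.where(rng.random(n) < 0.3, 1, -1)
        if not (y == 1).any():
            y[0] = 1
        s = np.round(rng.random(n), 2)
        t, achieved = threshold_at_precision(y, s, 0.75)
        # brute force over every cut point
        best = None
        for cut in np.unique(s):
            c = counts_at_threshold(y, s, cut)
            if c.tp + c.fp == 0:
                continue
            pre = c.tp / (c.tp + c.fp)
            rec = c.tp / (c.tp + c.fn)
            if pre >= 0.75 and (best is None or rec > best[0]):
                best = (rec, cut)
        if best is None:
            assert not achieved
        else:
            c = counts_at_threshold(y, s, t)
            assert c.tp / (c.tp + c.fn) == pytest.approx(best[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            threshold_at_precision(np.array([]), np.array([]))


class TestRocAuc:
    def test_perfect_ranking(self):
        assert roc_auc(np.array([1, -1, -1]), np.array([0.9, 0.1, 0.2])) == 1.0

    def test_tie_convention(self):
        assert roc_auc(np.array([1, -1]), np.array([0.5, 0.5])) == 0.5

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pair_counting(self, seed):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(30) < 0.4, 1, -1)
        y[0], y[1] = 1, -1
        s = np.round(rng.random(30), 1)  # coarse scores force ties
        pos = s[y == 1]
        neg = s[y == -1]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        assert roc_auc(y, s) == pytest.approx(wins / (len(pos) * len(neg)))

    def test_label_flip_symmetry(self, rng):
        y = np.where(rng.random(40) < 0.3, 1, -1)
        y[:2] = [1, -1]
        s = rng.random(40)
        assert roc_auc(y, s) == pytest.approx(1 - roc_auc(-y, s))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.ones(5), np.random.rand(5))


class TestAurpc:
    def test_perfect_classifier(self):
        y = np.array([1] * 5 + [-1] * 10)
        s = np.concatenate([np.linspace(0.9, 1.0, 5), np.linspace(0.0, 0.4, 10)])
        assert aurpc_davis_goadrich(y, s) == pytest.approx(1.0)

    def test_constant_scores_give_prevalence(self):
        y = np.array([1] * 3 + [-1] * 9)
        s = np.full(12, 0.5)
        assert aurpc_davis_goadrich(y, s) == pytest.approx(0.25)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_dense_interpolation_oracle(self, seed):
        rng = np.random.default_rng(seed)
        y = np.where(rng.random(20) < 0.4, 1, -1)
        y[0] = 1
        s = rng.random(20)
        # oracle: walk cut points, interpolate TP one unit at a time
        order = np.argsort(-s)
        ys = y[order]
        pts = []
        tp = fp = 0
        for i, label in enumerate(ys):
            tp += label == 1
            fp += label == -1
            if i + 1 < len(ys) and s[order[i + 1]] == s[order[i]]:
                continue
            pts.append((tp, fp))
        n_pos = int((y == 1).sum())
        curve = []
        ptp, pfp = 0, 0
        for tp, fp in pts:
            if tp > ptp:
                for t in range(ptp + 1, tp + 1):
                    f = pfp + (fp - pfp) * (t - ptp) / (tp - ptp)
                    curve.append((t / n_pos, t / (t + f)))
            elif tp > 0:
                curve.append((tp / n_pos, tp / (tp + fp)))
            ptp, pfp = tp, fp
        curve.insert(0, (0.0, curve[0][1]))
        rec = [r for r, _ in curve]
        pre = [p for _, p in curve]
        oracle = np.trapezoid(pre, rec)
        assert aurpc_davis_goadrich(y, s) == pytest.approx(oracle, abs=1e-6)

    def test_bounds(self, rng):
        y = np.where(rng.random(50) < 0.2, 1, -1)
        y[0] = 1
        v = aurpc_davis_goadrich(y, rng.random(50))
        assert 0.0 <= v <= 1.0

    def test_no_positives_rejected(self):
        with pytest.raises(ValueError):
            aurpc_davis_goadrich(np.array([-1, -1]), np.array([0.1, 0.2]))


class TestClassifier:
    def test_separable_training_auc(self, rng):
        X = rng.standard_normal((60, 2))
        y = np.where(X[:, 0] > 0, 1, -1)
        model = ZincSiteClassifier(n_estimators=50, random_state=0).fit(X, y)
        assert roc_auc(y, model.predict_scores(X)) == 1.0

    def test_seed_determinism(self, rng):
        X = rng.standard_normal((60, 4))
        y = np.where(rng.random(60) < 0.3, 1, -1)
        y[:2] = [1, -1]
        s1 = ZincSiteClassifier(n_estimators=50, random_state=7).fit(X, y).predict_scores(X)
        s2 = ZincSiteClassifier(n_estimators=50, random_state=7).fit(X, y).predict_scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError):
            ZincSiteClassifier().fit(rng.standard_normal((10, 2)), np.ones(10))

    def test_calibrated_threshold_used_by_predict(self, rng):
        X = rng.standard_normal((100, 2))
        y = np.where(X[:, 0] + 0.3 * rng.standard_normal(100) > 0.8, 1, -1)
        if len(np.unique(y)) < 2:
            pytest.skip("degenerate draw")
        model = ZincSiteClassifier(n_estimators=50, random_state=0).fit(X, y)
        thr = model.calibrate_threshold(X, y)
        pred = model.predict(X)
        np.testing.assert_array_equal(pred, np.where(model.predict_scores(X) >= thr, 1, -1))

    def test_sklearn_params_round_trip(self):
        model = ZincSiteClassifier(n_estimators=10, random_state=3)
        assert ZincSiteClassifier(**model.get_params()).get_params() == model.get_params()


def _preds(rows):
    frame = pd.DataFrame(rows, columns=["key", "label", "score", "chain_id",
                                        "residue_type"])
    frame = frame.set_index("key")
    return frame


class TestProteinLevel:
    def test_tp_requires_a_correct_binding_residue(self):
        preds = _preds([
            ("A:1", 1, 0.9, "A", "C"), ("A:2", 1, 0.1, "A", "H"),
            ("B:1", -1, 0.9, "B", "E"), ("B:2", 1, 0.1, "B", "D"),
            ("C:1", -1, 0.1, "C", "C"),
        ])
        truth = {"A": True, "B": True, "C": False}
        rep = protein_level(preds, truth, threshold=0.5)
        # A: binding residue predicted -> TP; B: only a non-binding residue
        # predicted -> FN; C: quiet non-binding chain -> TN
        assert (rep.confusion.tp, rep.confusion.fn) == (1, 1)
        assert (rep.confusion.fp, rep.confusion.tn) == (0, 1)

    def test_false_alarm_chain(self):
        preds = _preds([("A:1", 1, 0.9, "A", "C"),
                        ("B:1", -1, 0.8, "B", "H")])
        rep = protein_level(preds, {"A": True, "B": False}, threshold=0.5)
        assert rep.confusion.fp == 1

    def test_tp_bounded_by_binding_chains(self, rng):
        rows = []
        for c in "ABCDE":
            for i in range(4):
                rows.append((f"{c}:{i}", int(rng.choice([1, -1])),
                             float(rng.random()), c, "C"))
        preds = _preds(rows)
        truth = {c: bool((preds[preds.chain_id == c]["label"] == 1).any())
                 for c in "ABCDE"}
        rep = protein_level(preds, truth, threshold=0.5)
        assert rep.confusion.tp <= sum(truth.values())


class TestResidueReport:
    def test_per_type_counts_sum_to_total(self, rng):
        rows = []
        for i in range(80):
            rows.append((f"A:{i}", int(rng.choice([1, -1], p=[0.2, 0.8])),
                         float(rng.random()), "A", str(rng.choice(list("CHED")))))
        preds = _preds(rows)
        preds.iloc[0, preds.columns.get_loc("label")] = 1
        rep = evaluate_residue_level(preds)
        total = sum((sub.confusion.tp + sub.confusion.fp + sub.confusion.tn
                     + sub.confusion.fn) for sub in rep.per_type.values())
        assert total == rep.confusion.total
        tp = sum(sub.confusion.tp for sub in rep.per_type.values())
        assert tp == rep.confusion.tp
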
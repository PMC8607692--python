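"""Event logistic model and majority-vote cell classification."""

import numpy as np
import pytest

import sparkline as sl
from sparkline.characterize import SparkFeatures
from sparkline.classify import (
    CellRecord,
    EventGroupClassifier,
    UnclassifiableCellError,
)


def _event(amplitude=0.5, fwhm=2.0, fdhm=20.0, rise=4.0, t50=14.0, valid=True):
    return SparkFeatures(
        amplitude=amplitude, fwhm=fwhm, fdhm=fdhm, rise_time=rise, t50=t50,
        r2_spatial=0.9, r2_temporal=0.9,
        spatial_valid=valid, temporal_valid=valid)


def _cohort_events(rng, n, amp_mean):
    return [
        _event(amplitude=rng.normal(amp_mean, 0.08),
               fwhm=rng.normal(2.0, 0.2), fdhm=rng.normal(20, 2),
               rise=rng.normal(4, 0.5), t50=rng.normal(14, 1.5))
        for _ in range(n)
    ]


class TestFit:
    def test_separable_classes_learned_with_correct_sign(self, rng):
        X = np.column_stack([
            np.concatenate([rng.normal(-2, 0.1, 50), rng.normal(2, 0.1, 50)]),
            rng.normal(0, 1, 100), rng.normal(0, 1, 100),
            rng.normal(0, 1, 100), rng.normal(0, 1, 100)])
        y = np.array(["A"] * 50 + ["B"] * 50)
        clf = EventGroupClassifier().fit(X, y)
        assert (clf.predict(X) == y).mean() == 1.0
        assert clf.weights_[0] > 0  # positive weight points toward class B

    def test_matches_grid_search_oracle_on_tiny_dataset(self):
        # 6 events, one feature: penalized likelihood maximized by brute
        # force over (weight, intercept) must agree with the fit
        X = np.array([[-1.2], [-0.7], [-0.2], [0.3], [0.8], [1.3]])
        y = np.array(["A", "A", "B", "A", "B", "B"])
        l2 = 1e-3
        clf = EventGroupClassifier(l2=l2).fit(X, y)
        z = (X - clf.feature_means_) / clf.feature_sds_
        yb = (y == "B").astype(float)

        def neg_obj(w, b):
            logit = b + w * z[:, 0]
            ll = yb * logit - np.log1p(np.exp(logit))
            return -(ll.sum() - l2 / 2 * w**2)

        # coarse-to-fine grid search
        w_lo, w_hi, b_lo, b_hi = -20.0, 20.0, -10.0, 10.0
        for _ in range(6):
            ws = np.linspace(w_lo, w_hi, 81)
            bs = np.linspace(b_lo, b_hi, 81)
            vals = np.array([[neg_obj(w, b) for b in bs] for w in ws])
            i, j = np.unravel_index(vals.argmin(), vals.shape)
            w_best, b_best = ws[i], bs[j]
            w_span, b_span = (w_hi - w_lo) / 10, (b_hi - b_lo) / 10
            w_lo, w_hi = w_best - w_span, w_best + w_span
            b_lo, b_hi = b_best - b_span, b_best + b_span
        assert clf.weights_[0] == pytest.approx(w_best, abs=1e-3)
        assert clf.intercept_ == pytest.approx(b_best, abs=1e-3)

    def test_shuffled_labels_give_chance_accuracy(self, rng):
        X = rng.normal(0, 1, (1000, 5))
        y = rng.choice(["A", "B"], 1000)
        clf = EventGroupClassifier().fit(X, y)
        acc = (clf.predict(X) == y).mean()
        assert 0.45 <= acc <= 0.6

    def test_single_class_rejected(self, rng):
        X = rng.normal(0, 1, (10, 5))
        with pytest.raises(ValueError, match="two classes"):
            EventGroupClassifier().fit(X, np.array(["A"] * 10))

    def test_json_roundtrip_preserves_probabilities(self, rng):
        X = rng.normal(0, 1, (60, 5))
        y = np.where(X[:, 0] + rng.normal(0, 0.5, 60) > 0, "B", "A")
        clf = EventGroupClassifier().fit(X, y)
        clf2 = EventGroupClassifier.from_json(clf.to_json())
        np.testing.assert_array_equal(clf.predict_proba(X), clf2.predict_proba(X))


class TestClassifyEvent:
    def _fitted(self, rng):
        X = rng.normal(0, 1, (80, 5)) + 0.3
        y = np.where(X[:, 0] > 0.3, "B", "A")
        return EventGroupClassifier().fit(X, y)

    def test_event_at_training_mean_scores_logistic_intercept(self, rng):
        clf = self._fitted(rng)
        ev = _event(*clf.feature_means_)
        p, _ = sl.classify_event(clf, ev)
        assert p == pytest.approx(1 / (1 + np.exp(-clf.intercept_)), abs=1e-12)

    def test_probability_matches_hand_evaluated_formula(self, rng):
        clf = self._fitted(rng)
        ev = _event(0.37, 2.1, 19.0, 4.2, 13.0)
        feats = np.array([ev.amplitude, ev.fwhm, ev.fdhm, ev.rise_time, ev.t50])
        z = (feats - clf.feature_means_) / clf.feature_sds_
        expected = 1 / (1 + np.exp(-(clf.intercept_ + np.dot(clf.weights_, z))))
        p, label = sl.classify_event(clf, ev)
        assert p == pytest.approx(expected, abs=1e-12)
        assert label == ("B" if p >= 0.5 else "A")

    def test_zero_model_labels_b_at_exact_half(self):
        clf = EventGroupClassifier()
        clf.classes_ = np.array(["A", "B"])
        clf.weights_ = np.zeros(5)
        clf.intercept_ = 0.0
        clf.feature_means_ = np.zeros(5)
        clf.feature_sds_ = np.ones(5)
        p, label = sl.classify_event(clf, _event())
        assert p == 0.5 and label == "B"

    def test_invalid_event_excluded(self, rng):
        clf = self._fitted(rng)
        with pytest.raises(ValueError, match="invalid"):
            sl.classify_event(clf, _event(valid=False))


class TestClassifyCell:
    def _hand_classifier(self):
        # amplitude-only model: p(B) > 0.5 iff amplitude above 0.45
        clf = EventGroupClassifier()
        clf.classes_ = np.array(["A", "B"])
        clf.weights_ = np.array([10.0, 0, 0, 0, 0])
        clf.intercept_ = 0.0
        clf.feature_means_ = np.array([0.45, 2.0, 20.0, 4.0, 14.0])
        clf.feature_sds_ = np.array([0.1, 0.3, 3.0, 0.6, 2.0])
        return clf

    def _cell(self, amplitudes, group=None):
        return CellRecord(cell_id="c0",
                          events=[_event(amplitude=a) for a in amplitudes],
                          scan_length_um=70.0, duration_s=4.0, group=group)

    def test_strict_majority(self):
        cc = sl.classify_cell(self._hand_classifier(),
                              self._cell([0.3] * 7 + [0.6] * 3))
        assert cc.cell_label == "A" and not cc.tie_broken
        assert cc.margin == pytest.approx(0.4)
        assert cc.counts == {"A": 7, "B": 3}

    def test_tie_broken_by_probability_mass(self):
        # 5 weak A-votes vs 5 strong B-votes: B wins on summed probability
        cc = sl.classify_cell(self._hand_classifier(),
                              self._cell([0.44] * 5 + [0.7] * 5))
        assert cc.tie_broken and cc.cell_label == "B"

    def test_empty_cell_unclassifiable(self):
        with pytest.raises(UnclassifiableCellError):
            sl.classify_cell(self._hand_classifier(), self._cell([]))

    def test_frequency_formula(self):
        cell = self._cell([0.5] * 8)
        # 8 events / (70 um / 100) / 4 s
        assert cell.frequency == pytest.approx(8 / 0.7 / 4.0)


class TestEvaluateClassification:
    def test_perfect_classifier_scores_one_everywhere(self, rng):
        clf = TestClassifyCell()._hand_classifier()
        cells = [
            CellRecord("a1", [_event(amplitude=0.3)] * 5, 70, 4, group="A"),
            CellRecord("b1", [_event(amplitude=0.6)] * 5, 70, 4, group="B"),
        ]
        rep = sl.evaluate_classification(clf, cells)
        assert rep.event_accuracy == {"A": 1.0, "B": 1.0}
        assert rep.cell_accuracy == {"A": 1.0, "B": 1.0}
        assert rep.min_cell_event_accuracy == {"A": 1.0, "B": 1.0}

    def test_majority_vote_amplifies_event_accuracy(self, rng):
        # per-event accuracy built at 0.75; cells of 15 events: the binomial
        # tail P(Bin(15, .75) >= 8) ~ 0.996 predicts the cell accuracy
        from scipy.stats import binom
        clf = TestClassifyCell()._hand_classifier()
        cells = []
        for i in range(200):
            group = "A" if i % 2 == 0 else "B"
            correct = rng.random(15) < 0.75
            amps = np.where(correct ^ (group == "B"), 0.3, 0.6)
            cells.append(CellRecord(f"c{i}", [_event(amplitude=a) for a in amps],
                                    70, 4, group=group))
        rep = sl.evaluate_classification(clf, cells)
        expected = binom.sf(7, 15, 0.75)
        measured = np.mean([rep.cell_accuracy["A"], rep.cell_accuracy["B"]])
        assert measured == pytest.approx(expected, abs=0.02)

    def test_chance_events_give_chance_cells(self, rng):
        clf = TestClassifyCell()._hand_classifier()
        cells = []
        for i in range(300):
            group = "A" if i % 2 == 0 else "B"
            amps = np.where(rng.random(15) < 0.5, 0.3, 0.6)
            cells.append(CellRecord(f"c{i}", [_event(amplitude=a) for a in amps],
                                    70, 4, group=group))
        rep = sl.evaluate_classification(clf, cells)
        overall = np.mean([rep.cell_accuracy["A"], rep.cell_accuracy["B"]])
        assert 0.4 <= overall <= 0.6
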
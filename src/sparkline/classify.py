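"""Event-based logistic regression and majority-vote cell classification.

Each spark is classified into one of two condition groups from its
morphometrics (amplitude, FWHM, FDHM, rise time, t50 — spark frequency is a
cell-level quantity and deliberately not an event feature); a cell is then
labelled by majority vote over its events.  With independent events of
per-event accuracy p > 0.5, the vote amplifies accuracy following the
binomial tail P(Bin(n, p) > n/2), which is how ~75% event accuracy can
yield ~100% cell accuracy for cells with a dozen or more sparks.

The per-event model is an L2-penalized logistic regression on z-scored
features: p(B | z) = logistic(intercept + w . z).  Ties are documented
conventions: an event with p exactly 0.5 goes to class B; a cell with equal
vote counts goes to the class with the larger summed probability mass and
is flagged ``tie_broken``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression

from .characterize import FEATURE_NAMES, SparkFeatures


@dataclass
class CellRecord:
    """One cell's events, geometry and (optionally) its true group."""

    cell_id: str
    events: list[SparkFeatures]
    scan_length_um: float
    duration_s: float
    group: str | None = None

    @property
    def valid_events(self) -> list[SparkFeatures]:
        return [e for e in self.events if e.valid]

    @property
    def frequency(self) -> float:
        """Spark frequency in events / (100 um) / s."""
        return len(self.events) / (self.scan_length_um / 100.0) / self.duration_s


@dataclass
class CellClassification:
    cell_id: str
    event_probs: np.ndarray      # p(class B) per valid event
    event_labels: np.ndarray     # hard labels, elements of {class_a, class_b}
    counts: dict[str, int]
    cell_label: str
    tie_broken: bool
    margin: float                # |count_A - count_B| / total


class UnclassifiableCellError(ValueError):
    """Raised for a cell with no valid events."""


def _features_matrix(events: list[SparkFeatures]) -> np.ndarray:
    return np.array(
        [[e.amplitude, e.fwhm, e.fdhm, e.rise_time, e.t50] for e in events],
        dtype=np.float64,
    )


class EventGroupClassifier(BaseEstimator, ClassifierMixin):
    """L2-penalized logistic regression over z-scored spark features.

    Parameters
    ----------
    l2 : float
        Penalty strength on the weights (intercept unpenalized); the
        objective is ``sum of binomial deviance + l2/2 * ||w||^2``.  The
        small default keeps the fit finite under perfect separation.
    seed : int
        Recorded for provenance; the lbfgs fit itself is deterministic.

    Fitted attributes (trailing underscore): ``weights_``, ``intercept_``,
    ``feature_means_``, ``feature_sds_``, ``classes_``.
    """

    feature_names = list(FEATURE_NAMES)

    def __init__(self, l2: float = 1e-3, seed: int = 0):
        self.l2 = l2
        self.seed = seed

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError(f"need exactly two classes, got {classes!r}")
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_events, n_features)")
        self.n_features_in_ = X.shape[1]
        if not np.all(np.isfinite(X)):
            raise ValueError("X contains non-finite features; filter invalid events first")
        self.classes_ = classes
        self.feature_means_ = X.mean(axis=0)
        sds = X.std(axis=0, ddof=0)
        if np.any(sds == 0):
            raise ValueError("a feature has zero variance; cannot z-score")
        self.feature_sds_ = sds
        z = (X - self.feature_means_) / self.feature_sds_
        yb = (y == classes[1]).astype(int)
        # objective sum(deviance) + l2/2 ||w||^2  <=>  sklearn C = 1/l2
        lr = LogisticRegression(
            C=1.0 / self.l2, solver="lbfgs", tol=1e-10, max_iter=10000,
        )
        lr.fit(z, yb)
        self.weights_ = lr.coef_.ravel().copy()
        self.intercept_ = float(lr.intercept_[0])
        return self

    def decision_function(self, X):
        X = np.asarray(X, dtype=np.float64)
        z = (X - self.feature_means_) / self.feature_sds_
        return self.intercept_ + z @ self.weights_

    def predict_proba(self, X):
        p = 1.0 / (1.0 + np.exp(-self.decision_function(X)))
        return np.column_stack([1.0 - p, p])

    def predict(self, X):
        p = self.predict_proba(X)[:, 1]
        # ties at exactly 0.5 go to the second class (documented convention)
        return np.where(p >= 0.5, self.classes_[1], self.classes_[0])

    # -- serialization ------------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "feature_names": self.feature_names,
                "weights": self.weights_.tolist(),
                "intercept": self.intercept_,
                "feature_means": self.feature_means_.tolist(),
                "feature_sds": self.feature_sds_.tolist(),
                "classes": [str(c) for c in self.classes_],
                "l2": self.l2,
                "seed": self.seed,
            },
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventGroupClassifier":
        d = json.loads(text)
        clf = cls(l2=d["l2"], seed=d["seed"])
        clf.weights_ = np.array(d["weights"])
        clf.intercept_ = float(d["intercept"])
        clf.feature_means_ = np.array(d["feature_means"])
        clf.feature_sds_ = np.array(d["feature_sds"])
        clf.classes_ = np.array(d["classes"])
        return clf


# ---------------------------------------------------------------------------
# spec-surface wrappers

def fit_event_classifier(
    events: list[SparkFeatures],
    labels: list[str],
    l2: float = 1e-3,
    seed: int = 0,
) -> EventGroupClassifier:
    """Fit the per-event model from flagged-valid spark features."""
    keep = [i for i, e in enumerate(events) if e.valid]
    if len(keep) < len(events):
        pass  # invalid events are excluded, not imputed
    X = _features_matrix([events[i] for i in keep])
    y = np.asarray(labels)[keep]
    return EventGroupClassifier(l2=l2, seed=seed).fit(X, y)


def classify_event(clf: EventGroupClassifier, ev: SparkFeatures) -> tuple[float, str]:
    """Probability of the second class and hard label for one event."""
    if not ev.valid:
        raise ValueError("event has invalid fits; excluded from classification")
    X = _features_matrix([ev])
    p = float(clf.predict_proba(X)[0, 1])
    label = clf.classes_[1] if p >= 0.5 else clf.classes_[0]
    return p, str(label)


def classify_cell(clf: EventGroupClassifier, cell: CellRecord) -> CellClassification:
    """Majority vote over the cell's valid events."""
    events = cell.valid_events
    if not events:
        raise UnclassifiableCellError(f"{cell.cell_id}: no valid events")
    X = _features_matrix(events)
    probs = clf.predict_proba(X)[:, 1]
    labels = np.where(probs >= 0.5, clf.classes_[1], clf.classes_[0])
    ca, cb = str(clf.classes_[0]), str(clf.classes_[1])
    n_a = int(np.sum(labels == clf.classes_[0]))
    n_b = len(labels) - n_a
    tie = n_a == n_b
    if tie:
        # equal counts: the class with more summed probability mass wins
        mass_b = float(probs.sum())
        mass_a = float(len(probs) - mass_b)
        cell_label = cb if mass_b >= mass_a else ca
    else:
        cell_label = ca if n_a > n_b else cb
    return CellClassification(
        cell_id=cell.cell_id,
        event_probs=probs,
        event_labels=labels.astype(str),
        counts={ca: n_a, cb: n_b},
        cell_label=cell_label,
        tie_broken=tie,
        margin=abs(n_a - n_b) / len(labels),
    )


@dataclass
class ClassificationReport:
    event_accuracy: dict[str, float]      # per true group
    cell_accuracy: dict[str, float]       # per true group
    min_cell_event_accuracy: dict[str, float]
    n_events: dict[str, int]
    n_cells: dict[str, int]
    per_cell: pd.DataFrame


def evaluate_classification(
    clf: EventGroupClassifier, cohort: list[CellRecord]
) -> ClassificationReport:
    """Event- and cell-level accuracies per true group.

    Event accuracy is the fraction of events whose hard label matches the
    cell's true group; cell accuracy the fraction of cells whose majority
    label matches; the per-group minimum of per-cell event accuracy is the
    worst single cell.
    """
    rows = []
    for cell in cohort:
        if cell.group is None:
            raise ValueError(f"{cell.cell_id} has no true group label")
        cc = classify_cell(clf, cell)
        ev_correct = float(np.mean(cc.event_labels == cell.group))
        rows.append(
            {
                "cell_id": cell.cell_id, "group": cell.group,
                "n_events": len(cc.event_labels),
                "event_accuracy": ev_correct,
                "cell_label": cc.cell_label,
                "cell_correct": cc.cell_label == cell.group,
                "tie_broken": cc.tie_broken, "margin": cc.margin,
                "frequency": cell.frequency,
            }
        )
    df = pd.DataFrame(rows)
    event_acc, cell_acc, min_acc, n_ev, n_cells = {}, {}, {}, {}, {}
    for g, sub in df.groupby("group"):
        weights = sub["n_events"].to_numpy()
        event_acc[g] = float(np.average(sub["event_accuracy"], weights=weights))
        cell_acc[g] = float(sub["cell_correct"].mean())
        min_acc[g] = float(sub["event_accuracy"].min())
        n_ev[g] = int(weights.sum())
        n_cells[g] = int(len(sub))
    return ClassificationReport(
        event_accuracy=event_acc, cell_accuracy=cell_acc,
        min_cell_event_accuracy=min_acc, n_events=n_ev, n_cells=n_cells,
        per_cell=df,
    )
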
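"""Rear-end collision-risk classification of automotive warning events.

A *warning event* is an episode during which a truck's inter-vehicle-distance
or anti-collision alarm sounds; each event is summarised by six vehicle-
behaviour features (duration of the alarm and speed statistics over it) and
classified as collision-risk (1) or non-risk (0).  Two classifiers are
provided, both sklearn estimators:

* :class:`RuleRiskClassifier` — the published axis-aligned rule set
  (an event is risky when the alarm persists, either at highway speed with
  moderate speed oscillation, or at congestion speed);
* :class:`CartRiskClassifier` — a CART decision tree fitted to annotated
  events with 5-fold cross-validated grid search over depth and leaf size.

Risk-classified events are then aggregated per driver-day into the exposure-
normalised daily collision risk index ``R_1hr = R / WT`` (risk events per
driving hour); days with less than three hours of driving are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "FEATURE_NAMES",
    "WarningEvent",
    "EventFeatures",
    "DriverDay",
    "EvaluationResult",
    "extract_features",
    "rule_classify",
    "RuleRiskClassifier",
    "CartRiskClassifier",
    "train_tree",
    "evaluate",
    "evaluate_model",
    "daily_index",
]

#: Column order used whenever features are passed as a plain matrix.
FEATURE_NAMES: Tuple[str, ...] = (
    "duration_s",
    "max_speed_kmh",
    "min_speed_kmh",
    "avg_speed_kmh",
    "speed_sd_kmh",
    "max_decel_kmh_s",
)


@dataclass(frozen=True)
class WarningEvent:
    """One alarm episode: 1 Hz speed samples over its duration."""

    speed_samples: np.ndarray
    duration_s: float
    driver_id: str = ""
    date: str = ""
    start_time: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.speed_samples, dtype=float)
        object.__setattr__(self, "speed_samples", arr)
        if self.duration_s <= 0:
            raise ValueError("event duration must be positive")


@dataclass(frozen=True)
class EventFeatures:
    duration_s: float
    max_speed_kmh: float
    min_speed_kmh: float
    avg_speed_kmh: float
    speed_sd_kmh: float
    max_decel_kmh_s: float

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, name) for name in FEATURE_NAMES])


def extract_features(event: WarningEvent) -> EventFeatures:
    """Summarise an event's speed trace into the six behaviour features.

    Speed statistics are max/min/mean and the (population) standard
    deviation of the 1 Hz samples; ``max_decel_kmh_s`` is the largest
    one-second speed drop, floored at zero.  Traces whose sample count is
    inconsistent with 1 Hz sampling (beyond +-1 sample) are resampled to
    1 Hz by linear interpolation first.
    """
    s = np.asarray(event.speed_samples, dtype=float)
    if s.size < 2:
        raise ValueError("need at least 2 speed samples to extract features")
    n_expected = int(round(event.duration_s))
    if abs(s.size - n_expected) > 1:
        t_have = np.linspace(0.0, event.duration_s, s.size)
        t_want = np.arange(0.0, np.floor(event.duration_s) + 1.0)
        s = np.interp(t_want, t_have, s)
    drops = s[:-1] - s[1:]
    return EventFeatures(
        duration_s=float(event.duration_s),
        max_speed_kmh=float(s.max()),
        min_speed_kmh=float(s.min()),
        avg_speed_kmh=float(s.mean()),
        speed_sd_kmh=float(s.std()),
        max_decel_kmh_s=float(max(0.0, drops.max())),
    )


def rule_classify(
    f: EventFeatures,
    *,
    duration_long: float = 79.0,
    duration_mid: float = 42.5,
    sd_low: float = 5.8,
    sd_high: float = 6.5,
    speed_split: float = 39.0,
) -> int:
    """Published rule set for collision risk.

    An event is risky (1) when either rule fires:

    * sustained highway alarm: duration > 79.0 s, speed deviation in
      (5.8, 6.5] km/h, maximum speed > 39 km/h;
    * sustained congestion alarm: duration > 42.5 s, maximum speed < 39 km/h.

    Comparators follow the CART split convention (left branch is <=), so
    "greater than" is strict and the upper deviation bound is inclusive.
    """
    highway = (
        f.duration_s > duration_long
        and sd_low < f.speed_sd_kmh <= sd_high
        and f.max_speed_kmh > speed_split
    )
    congestion = f.duration_s > duration_mid and f.max_speed_kmh < speed_split
    return int(highway or congestion)


def _as_feature_matrix(X) -> np.ndarray:
    """Accept EventFeatures sequences, DataFrames or plain matrices."""
    if hasattr(X, "loc"):  # DataFrame
        missing = [c for c in FEATURE_NAMES if c not in X.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        return X.loc[:, list(FEATURE_NAMES)].to_numpy(dtype=float)
    X = list(X) if not isinstance(X, np.ndarray) else X
    if len(X) and isinstance(X[0], EventFeatures):
        return np.vstack([f.as_array() for f in X])
    arr = np.asarray(X, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != len(FEATURE_NAMES):
        raise ValueError(
            f"expected matrix with {len(FEATURE_NAMES)} feature columns "
            f"in order {FEATURE_NAMES}"
        )
    return arr


class RuleRiskClassifier(ClassifierMixin, BaseEstimator):
    """The printed collision-risk rule set as a (parameter-free) estimator.

    ``fit`` is a no-op kept for pipeline compatibility; thresholds are
    estimator parameters so the rule geometry can be varied in sensitivity
    analyses.
    """

    def __init__(
        self,
        duration_long: float = 79.0,
        duration_mid: float = 42.5,
        sd_low: float = 5.8,
        sd_high: float = 6.5,
        speed_split: float = 39.0,
    ):
        self.duration_long = duration_long
        self.duration_mid = duration_mid
        self.sd_low = sd_low
        self.sd_high = sd_high
        self.speed_split = speed_split

    def fit(self, X=None, y=None):
        self.classes_ = np.array([0, 1])
        return self

    def predict(self, X) -> np.ndarray:
        M = _as_feature_matrix(X)
        dur, vmax, sd = M[:, 0], M[:, 1], M[:, 4]
        highway = (
            (dur > self.duration_long)
            & (sd > self.sd_low)
            & (sd <= self.sd_high)
            & (vmax > self.speed_split)
        )
        congestion = (dur > self.duration_mid) & (vmax < self.speed_split)
        return (highway | congestion).astype(int)


class CartRiskClassifier(ClassifierMixin, BaseEstimator):
    """CART collision-risk classifier with cross-validated grid search.

    Fits a Gini-impurity decision tree; maximum depth and minimum leaf size
    are chosen by grid search maximising mean accuracy over stratified
    k-fold cross-validation (default 5 folds).  Fold shuffling and tree
    tie-breaks are controlled by ``random_state`` and recorded in
    ``metadata_``.

    Attributes (after fit): ``best_estimator_``, ``best_params_``,
    ``cv_mean_accuracy_``, ``metadata_``, ``classes_``.
    """

    def __init__(
        self,
        max_depth_grid: Sequence[int] = (1, 2, 3, 4, 5, 6),
        min_samples_leaf_grid: Sequence[int] = (1, 5, 10),
        cv: int = 5,
        class_weight=None,
        random_state: int | None = 0,
    ):
        self.max_depth_grid = max_depth_grid
        self.min_samples_leaf_grid = min_samples_leaf_grid
        self.cv = cv
        self.class_weight = class_weight
        self.random_state = random_state

    def fit(self, X, y):
        M = _as_feature_matrix(X)
        y = np.asarray(y, dtype=int)
        if M.shape[0] != y.size:
            raise ValueError("X and y lengths differ")
        classes = np.unique(y)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if y.size < self.cv:
            raise ValueError(f"need at least cv={self.cv} samples")
        grid = {
            "max_depth": list(self.max_depth_grid),
            "min_samples_leaf": list(self.min_samples_leaf_grid),
        }
        folds = StratifiedKFold(
            n_splits=self.cv, shuffle=True, random_state=self.random_state
        )
        search = GridSearchCV(
            DecisionTreeClassifier(
                criterion="gini",
                class_weight=self.class_weight,
                random_state=self.random_state,
            ),
            grid,
            cv=folds,
            scoring="accuracy",
        )
        search.fit(M, y)
        self.best_estimator_ = search.best_estimator_
        self.best_params_ = dict(search.best_params_)
        self.cv_mean_accuracy_ = float(search.best_score_)
        self.classes_ = classes
        self.metadata_ = {
            "cv_folds": self.cv,
            "grid": grid,
            "random_state": self.random_state,
            "chosen": self.best_params_,
            "cv_mean_accuracy": self.cv_mean_accuracy_,
        }
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "best_estimator_")
        return self.best_estimator_.predict(_as_feature_matrix(X)).astype(int)

    def to_dict(self) -> dict:
        """Serialize the fitted tree (splits/thresholds/leaves) + metadata."""
        check_is_fitted(self, "best_estimator_")
        t = self.best_estimator_.tree_
        nodes = []
        for i in range(t.node_count):
            if t.children_left[i] == -1:  # leaf
                counts = t.value[i][0]
                nodes.append(
                    {
                        "node": i,
                        "leaf": True,
                        "label": int(np.argmax(counts)),
                        "counts": [float(c) for c in counts],
                    }
                )
            else:
                nodes.append(
                    {
                        "node": i,
                        "leaf": False,
                        "feature": FEATURE_NAMES[t.feature[i]],
                        "threshold": float(t.threshold[i]),
                        "left": int(t.children_left[i]),
                        "right": int(t.children_right[i]),
                    }
                )
        return {"nodes": nodes, "metadata": self.metadata_}


def train_tree(
    features: Iterable[EventFeatures], labels: Sequence[int], cfg: dict | None = None
) -> CartRiskClassifier:
    """Convenience wrapper: fit a :class:`CartRiskClassifier`."""
    clf = CartRiskClassifier(**(cfg or {}))
    return clf.fit(list(features), labels)


@dataclass(frozen=True)
class EvaluationResult:
    """Confusion matrix (predicted x actual) and headline rates.

    ``baseline_precision`` is the precision of the raw alarm itself — the
    fraction of all warnings that are actual collision risks — the comparator
    a trained classifier must beat.
    """

    confusion: np.ndarray  # [predicted, actual]
    accuracy: float
    baseline_precision: float
    n: int

    @property
    def accuracy_pct(self) -> float:
        return 100.0 * self.accuracy

    @property
    def baseline_precision_pct(self) -> float:
        return 100.0 * self.baseline_precision

    @classmethod
    def from_confusion(cls, tp: int, fn: int, fp: int, tn: int) -> "EvaluationResult":
        """Build from counts: tp/fn are actual positives predicted 1/0,
        fp/tn actual negatives predicted 1/0."""
        n = tp + fn + fp + tn
        if n == 0:
            raise ValueError("empty confusion matrix")
        conf = np.array([[tn, fn], [fp, tp]], dtype=int)
        return cls(
            confusion=conf,
            accuracy=(tp + tn) / n,
            baseline_precision=(tp + fn) / n,
            n=n,
        )


def evaluate(y_true: Sequence[int], y_pred: Sequence[int]) -> EvaluationResult:
    """Score predictions against annotated labels."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.size == 0:
        raise ValueError("empty test set")
    if y_true.shape != y_pred.shape:
        raise ValueError("prediction/label lengths differ")
    if not (np.isin(y_true, (0, 1)).all() and np.isin(y_pred, (0, 1)).all()):
        raise ValueError("labels must be binary 0/1")
    tp = int(np.sum((y_pred == 1) & (y_true == 1)))
    fn = int(np.sum((y_pred == 0) & (y_true == 1)))
    fp = int(np.sum((y_pred == 1) & (y_true == 0)))
    tn = int(np.sum((y_pred == 0) & (y_true == 0)))
    return EvaluationResult.from_confusion(tp, fn, fp, tn)


def evaluate_model(model, X, y_true) -> EvaluationResult:
    return evaluate(y_true, model.predict(X))


@dataclass(frozen=True)
class DriverDay:
    """Daily risk exposure: R risk events over WT driving hours."""

    driver_id: str
    date: str
    R: int
    wt_hours: float
    r_1hr: float
    included: bool


def daily_index(
    labels: Sequence[int], wt_hours: float, driver_id: str = "", date: str = ""
) -> DriverDay:
    """Aggregate one day's event labels into the daily collision risk index.

    ``R`` counts risk-classified events, ``r_1hr = R / wt_hours``.  Days with
    under three driving hours are marked excluded (their index never enters
    downstream statistics).
    """
    if wt_hours <= 0:
        raise ValueError("wt_hours must be positive")
    labels = np.asarray(labels, dtype=int)
    R = int(np.sum(labels == 1))
    included = wt_hours >= 3.0
    return DriverDay(
        driver_id=driver_id,
        date=date,
        R=R,
        wt_hours=float(wt_hours),
        r_1hr=R / wt_hours if included else float("nan"),
        included=included,
    )
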
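"""Warning-event features, rule/CART classification and the daily risk index."""

import numpy as np
import pytest

from fatiguerisk.risk import (
    CartRiskClassifier,
    EvaluationResult,
    EventFeatures,
    RuleRiskClassifier,
    WarningEvent,
    daily_index,
    evaluate,
    evaluate_model,
    extract_features,
    rule_classify,
    train_tree,
)
from fatiguerisk.synthetic import generate_events


def feats(duration, vmax, sd, vmin=20.0, avg=30.0, decel=2.0):
    return EventFeatures(
        duration_s=duration,
        max_speed_kmh=vmax,
        min_speed_kmh=vmin,
        avg_speed_kmh=avg,
        speed_sd_kmh=sd,
        max_decel_kmh_s=decel,
    )


class TestExtractFeatures:
    def test_constant_speed(self):
        ev = WarningEvent(speed_samples=np.full(10, 50.0), duration_s=10.0)
        f = extract_features(ev)
        assert (f.duration_s, f.max_speed_kmh, f.min_speed_kmh) == (10.0, 50.0, 50.0)
        assert (f.avg_speed_kmh, f.speed_sd_kmh, f.max_decel_kmh_s) == (50.0, 0.0, 0.0)

    def test_max_decel_is_largest_one_second_drop(self):
        ev = WarningEvent(speed_samples=np.array([60.0, 55.0, 49.0]), duration_s=3.0)
        assert extract_features(ev).max_decel_kmh_s == 6.0

    def test_acceleration_only_gives_zero_decel(self):
        ev = WarningEvent(speed_samples=np.array([40.0, 45.0, 52.0]), duration_s=3.0)
        assert extract_features(ev).max_decel_kmh_s == 0.0

    def test_known_statistics(self):
        s = np.array([30.0, 40.0, 30.0, 20.0, 30.0, 40.0, 30.0, 20.0])
        f = extract_features(WarningEvent(speed_samples=s, duration_s=8.0))
        assert f.avg_speed_kmh == pytest.approx(30.0)
        assert f.speed_sd_kmh == pytest.approx(np.sqrt(50.0))
        assert (f.max_speed_kmh, f.min_speed_kmh) == (40.0, 20.0)

    def test_non_1hz_trace_resampled(self):
        # 2 Hz samples over 10 s: statistics computed on the 1 Hz resample
        t = np.linspace(0.0, 10.0, 21)
        ev = WarningEvent(speed_samples=50.0 + 5.0 * t, duration_s=10.0)
        f = extract_features(ev)
        assert f.duration_s == 10.0
        assert f.max_speed_kmh == pytest.approx(100.0)
        assert f.min_speed_kmh == pytest.approx(50.0)

    def test_too_few_samples_is_error(self):
        with pytest.raises(ValueError, match="2"):
            extract_features(WarningEvent(speed_samples=np.array([50.0]), duration_s=1.0))


class TestRuleClassify:
    def test_highway_rule_fires(self):
        assert rule_classify(feats(80.0, 45.0, 6.0)) == 1

    def test_congestion_rule_fires_any_deviation(self):
        assert rule_classify(feats(50.0, 35.0, 1.0)) == 1
        assert rule_classify(feats(50.0, 35.0, 12.0)) == 1

    def test_published_example_event_is_not_risk(self):
        # duration 13 s fails both duration conditions
        f = EventFeatures(13.0, 87.0, 34.0, 56.0, 6.0, 3.0)
        assert rule_classify(f) == 0

    @pytest.mark.parametrize(
        "f, expected",
        [
            (feats(79.0, 45.0, 6.0), 0),   # duration must exceed 79 strictly
            (feats(80.0, 45.0, 5.8), 0),   # deviation must exceed 5.8 strictly
            (feats(80.0, 45.0, 6.5), 1),   # upper deviation bound inclusive
            (feats(80.0, 39.0, 6.0), 0),   # max speed must exceed 39 strictly
            (feats(42.5, 35.0, 1.0), 0),   # congestion duration strict
            (feats(43.0, 39.0, 1.0), 0),   # congestion max speed strictly below
        ],
    )
    def test_comparator_orientation(self, f, expected):
        assert rule_classify(f) == expected

    def test_estimator_matches_scalar_rule(self):
        rng = np.random.default_rng(4)
        M = np.column_stack(
            [
                rng.uniform(1, 160, 300),
                rng.uniform(10, 110, 300),
                rng.uniform(5, 60, 300),
                rng.uniform(10, 90, 300),
                rng.uniform(0, 12, 300),
                rng.uniform(0, 15, 300),
            ]
        )
        clf = RuleRiskClassifier().fit()
        vec = clf.predict(M)
        scalar = [rule_classify(EventFeatures(*row)) for row in M]
        assert np.array_equal(vec, scalar)


class TestCart:
    def test_single_class_rejected(self):
        X = [feats(10.0, 50.0, 1.0)] * 10
        with pytest.raises(ValueError, match="both classes"):
            CartRiskClassifier().fit(X, [0] * 10)

    def test_fewer_samples_than_folds_rejected(self):
        X = [feats(10.0, 50.0, 1.0), feats(50.0, 35.0, 1.0)]
        with pytest.raises(ValueError, match="cv"):
            CartRiskClassifier(cv=5).fit(X, [0, 1])

    def test_flipped_labels_learn_negated_rules(self):
        events = generate_events(285, 40 / 285, 0.0, seed=2)
        X = [extract_features(g.event) for g in events]
        y = [1 - g.rule_label for g in events]
        clf = CartRiskClassifier(random_state=0).fit(X, y)
        test = generate_events(400, 0.4, 0.0, seed=1002)
        Xt = [extract_features(g.event) for g in test]
        yt = np.array([1 - g.rule_label for g in test])
        assert (clf.predict(Xt) == yt).mean() >= 0.99

    def test_depth_one_grid_no_better_than_full_grid(self):
        events = generate_events(285, 40 / 285, 0.0, seed=3)
        X = [extract_features(g.event) for g in events]
        y = [g.label for g in events]
        stump = CartRiskClassifier(max_depth_grid=(1,), random_state=0).fit(X, y)
        full = CartRiskClassifier(random_state=0).fit(X, y)
        assert stump.cv_mean_accuracy_ <= full.cv_mean_accuracy_

    def test_deterministic_given_seed(self):
        events = generate_events(200, 0.3, 0.1, seed=5)
        X = [extract_features(g.event) for g in events]
        y = [g.label for g in events]
        p1 = train_tree(X, y, {"random_state": 7}).predict(X)
        p2 = train_tree(X, y, {"random_state": 7}).predict(X)
        assert np.array_equal(p1, p2)

    def test_json_serialization_round_trips_structure(self):
        events = generate_events(200, 0.3, 0.0, seed=6)
        X = [extract_features(g.event) for g in events]
        clf = CartRiskClassifier(random_state=0).fit(X, [g.label for g in events])
        d = clf.to_dict()
        assert {"nodes", "metadata"} <= set(d)
        assert d["metadata"]["cv_folds"] == 5
        leaves = [n for n in d["nodes"] if n["leaf"]]
        splits = [n for n in d["nodes"] if not n["leaf"]]
        assert len(leaves) == len(splits) + 1
        assert all(n["label"] in (0, 1) for n in leaves)


class TestEvaluate:
    def test_published_confusion_matrix(self):
        res = EvaluationResult.from_confusion(tp=4, fn=2, fp=2, tn=17)
        assert res.accuracy_pct == pytest.approx(84.0)
        assert res.baseline_precision_pct == pytest.approx(24.0)
        assert res.n == 25

    def test_perfect_predictions(self):
        y = np.array([0, 1, 1, 0, 1])
        res = evaluate(y, y)
        assert res.accuracy == 1.0
        assert res.confusion[0, 1] == 0 and res.confusion[1, 0] == 0

    def test_accuracy_complements_error_counts(self):
        rng = np.random.default_rng(0)
        yt = rng.integers(0, 2, 200)
        yp = rng.integers(0, 2, 200)
        res = evaluate(yt, yp)
        fp = res.confusion[1, 0]
        fn = res.confusion[0, 1]
        assert res.accuracy == pytest.approx(1.0 - (fp + fn) / res.n)

    def test_baseline_ignores_predictions(self):
        yt = np.array([1, 1, 0, 0, 0, 0])
        a = evaluate(yt, np.zeros(6, dtype=int))
        b = evaluate(yt, np.ones(6, dtype=int))
        assert a.baseline_precision == b.baseline_precision == pytest.approx(2 / 6)

    def test_empty_test_set_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            evaluate([], [])

    def test_evaluate_model_wrapper(self):
        events = generate_events(60, 0.5, 0.0, seed=9)
        X = [extract_features(g.event) for g in events]
        y = [g.rule_label for g in events]
        res = evaluate_model(RuleRiskClassifier().fit(), X, y)
        assert res.accuracy == 1.0


class TestDailyIndex:
    def test_basic_index(self):
        day = daily_index([1] * 8 + [0] * 3, wt_hours=4.0)
        assert (day.R, day.r_1hr, day.included) == (8, 2.0, True)

    def test_short_shift_excluded(self):
        day = daily_index([1] * 5, wt_hours=2.5)
        assert not day.included and np.isnan(day.r_1hr)

    def test_zero_events(self):
        day = daily_index([], wt_hours=10.0)
        assert day.R == 0 and day.r_1hr == 0.0

    def test_nonpositive_hours_is_error(self):
        with pytest.raises(ValueError):
            daily_index([1], wt_hours=-1.0)

    def test_index_times_hours_recovers_count_and_order_invariance(self):
        rng = np.random.default_rng(1)
        labels = rng.integers(0, 2, 40)
        day = daily_index(labels, wt_hours=7.3)
        assert day.r_1hr * day.wt_hours == pytest.approx(day.R)
        shuffled = daily_index(rng.permutation(labels), wt_hours=7.3)
        assert shuffled.r_1hr == day.r_1hr
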
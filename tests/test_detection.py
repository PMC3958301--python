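"""SVM epoch classifier, leave-one-record-out CV, and detection metrics."""

import warnings

import numpy as np
import pytest

from eegreduce.detection_eval import (ClassifierSpec, LabeledFeatureSet,
                                      compute_metrics, loro_cv, predict,
                                      train)
from eegreduce.features import EpochLabel
from eegreduce.synthetic_eeg import SeizureEvent

S, N, M = EpochLabel.SEIZURE, EpochLabel.NONSEIZURE, EpochLabel.MIXED


def _set(labels, events=(), record_id="r", epoch_s=4.0, features=None,
         rng=None):
    labels = np.array(labels, dtype=object)
    if features is None:
        rng = rng or np.random.default_rng(0)
        base = np.array([3.0 if lab == S else 0.0 for lab in labels])
        features = base[:, None] + 0.1 * rng.standard_normal((len(labels), 4))
    return LabeledFeatureSet(features=features, labels=labels,
                             record_id=record_id, epoch_duration_s=epoch_s,
                             events=list(events))


def recount_oracle(predictions, record_sets):
    """Brute-force re-derivation of all five metrics from the definitions."""
    tp = fp = tn = fn = 0
    detected, total = 0, 0
    lats = []
    for pred, rs in zip(predictions, record_sets):
        total += len(rs.events)
        if pred is None:
            continue
        for i, lab in enumerate(rs.labels):
            if lab == M:
                continue
            if lab == S and pred[i]:
                tp += 1
            elif lab == S:
                fn += 1
            elif pred[i]:
                fp += 1
            else:
                tn += 1
        for ev in rs.events:
            first = None
            for i, lab in enumerate(rs.labels):
                t0 = i * rs.epoch_duration_s
                t1 = t0 + rs.epoch_duration_s
                if (lab == S and pred[i] and t0 >= ev.onset_s - 1e-9
                        and t1 <= ev.offset_s + 1e-9):
                    first = t1
                    break
            if first is not None:
                detected += 1
                lats.append(first - ev.onset_s)
    out = {}
    out["seizure_sensitivity"] = 100 * detected / total if total else np.nan
    out["epoch_sensitivity"] = 100 * tp / (tp + fn) if tp + fn else np.nan
    out["specificity"] = 100 * tn / (tn + fp) if tn + fp else np.nan
    out["fpr_per_hour"] = (fp / ((tn + fp) * record_sets[0].epoch_duration_s
                                 / 3600) if tn + fp else np.nan)
    out["mean_latency_s"] = float(np.mean(lats)) if lats else np.nan
    return out


def _random_configuration(rng):
    """Random per-record labels/events/predictions, mutually consistent."""
    sets, preds = [], []
    for r in range(int(rng.integers(1, 4))):
        n_ep = int(rng.integers(8, 40))
        epoch_s = 4.0
        events = []
        t = 0.0
        for _ in range(int(rng.integers(0, 3))):
            onset = t + float(rng.uniform(1, 20))
            offset = onset + float(rng.uniform(5, 30))
            if offset >= n_ep * epoch_s:
                break
            events.append(SeizureEvent(onset, offset))
            t = offset
        labels = []
        for i in range(n_ep):
            lo, hi = i * epoch_s, (i + 1) * epoch_s
            if any(lo >= e.onset_s and hi <= e.offset_s for e in events):
                labels.append(S)
            elif any(lo < e.offset_s and hi > e.onset_s for e in events):
                labels.append(M)
            else:
                labels.append(N)
        sets.append(_set(labels, events, record_id=f"r{r}",
                         features=np.zeros((n_ep, 2))))
        preds.append(rng.integers(0, 2, n_ep))
    return preds, sets


class TestClassifier:
    def test_separable_toy_set_fits_perfectly(self, rng):
        x = np.vstack([rng.normal(-3, 0.3, (40, 2)),
                       rng.normal(3, 0.3, (40, 2))])
        y = np.array([0] * 40 + [1] * 40)
        model = train(x, y)
        assert np.array_equal(predict(model, x), y)

    def test_permuted_labels_score_at_chance(self):
        # balanced random features, 500 epochs, 5-fold CV: accuracy within
        # 3 binomial sigma of 50%
        rng = np.random.default_rng(77)
        x = rng.standard_normal((500, 8))
        y = np.array([0, 1] * 250)
        folds = np.arange(500) % 5
        correct = 0
        for f in range(5):
            model = train(x[folds != f], y[folds != f])
            correct += int((predict(model, x[folds == f]) ==
                            y[folds == f]).sum())
        acc = correct / 500
        assert abs(acc - 0.5) <= 3 * np.sqrt(0.25 / 500)

    def test_training_is_deterministic(self, rng):
        x = rng.standard_normal((60, 5))
        y = np.array([0, 1] * 30)
        p1 = predict(train(x, y), x)
        p2 = predict(train(x, y), x)
        assert np.array_equal(p1, p2)

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValueError, match="both classes"):
            train(rng.standard_normal((10, 3)), np.zeros(10, dtype=int))

    def test_mixed_labels_rejected(self, rng):
        with pytest.raises(ValueError, match="MIXED"):
            train(rng.standard_normal((4, 2)), [S, N, M, S])

    def test_all_zero_feature_row_predicts_without_error(self, rng):
        x = np.vstack([rng.normal(-2, 0.3, (20, 3)),
                       rng.normal(2, 0.3, (20, 3))])
        y = np.array([0] * 20 + [1] * 20)
        assert predict(train(x, y), np.zeros((1, 3)))[0] in (0, 1)


class TestLoroCv:
    def test_each_record_tested_once(self):
        sets = [_set([S, N, N, S, N], record_id=f"r{i}") for i in range(3)]
        preds = loro_cv(sets)
        assert len(preds) == 3
        assert all(p is not None and len(p) == 5 for p in preds)

    def test_record_order_invariance(self):
        sets = [_set([S, N, N, S, N], record_id=f"r{i}",
                     rng=np.random.default_rng(i)) for i in range(3)]
        preds = loro_cv(sets)
        rev = loro_cv(sets[::-1])
        assert all(np.array_equal(a, b) for a, b in zip(preds, rev[::-1]))

    def test_single_class_fold_skipped_with_warning(self):
        sets = [_set([S, N, N]), _set([N, N, N], record_id="r2"),
                _set([N, N, N, N], record_id="r3")]
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            preds = loro_cv(sets)
        # removing record 0 leaves no seizure epochs to train on
        assert preds[0] is None
        assert preds[1] is not None and preds[2] is not None
        assert any("single-class" in str(w.message) for w in caught)

    def test_two_records_required(self):
        with pytest.raises(ValueError):
            loro_cv([_set([S, N])])


class TestMetrics:
    def test_perfect_detection_with_4s_latency(self):
        # one event covering epochs 2-4 (8 s .. 20 s); the first seizure
        # epoch ends 4 s after onset
        labels = [N, N, S, S, S, N]
        rs = _set(labels, events=[SeizureEvent(8.0, 20.0)])
        pred = np.array([0, 0, 1, 1, 1, 0])
        rep = compute_metrics([pred], [rs])
        assert rep.seizure_sensitivity == 100.0
        assert rep.epoch_sensitivity == 100.0
        assert rep.specificity == 100.0
        assert rep.fpr_per_hour == 0.0
        assert rep.mean_latency_s == pytest.approx(4.0)

    def test_all_nonseizure_predictions(self):
        rs = _set([N, S, S, N], events=[SeizureEvent(4.0, 12.0)])
        rep = compute_metrics([np.zeros(4, dtype=int)], [rs])
        assert rep.seizure_sensitivity == 0.0
        assert rep.specificity == 100.0
        assert rep.fpr_per_hour == 0.0
        assert np.isnan(rep.mean_latency_s)

    def test_single_false_positive_rate(self):
        # 1 FP among 900 non-seizure epochs of 4 s -> 1 per hour
        labels = [N] * 900
        pred = np.zeros(900, dtype=int)
        pred[17] = 1
        rep = compute_metrics([pred], [_set(labels,
                                            features=np.zeros((900, 2)))])
        assert rep.fpr_per_hour == pytest.approx(1.0)

    def test_mixed_epochs_excluded_from_counts(self):
        rs = _set([N, M, S, M, N], events=[SeizureEvent(7.0, 13.0)])
        pred = np.array([0, 1, 1, 1, 0])
        rep = compute_metrics([pred], [rs])
        assert rep.tp_epochs == 1 and rep.fp_epochs == 0
        assert rep.tn_epochs == 2 and rep.fn_epochs == 0

    def test_no_nonseizure_epochs_reported_missing(self):
        rs = _set([S, S], events=[SeizureEvent(0.0, 8.0)])
        rep = compute_metrics([np.ones(2, dtype=int)], [rs])
        assert np.isnan(rep.specificity) and np.isnan(rep.fpr_per_hour)

    def test_matches_recount_oracle_on_random_configurations(self):
        rng = np.random.default_rng(123)
        for _ in range(100):
            preds, sets = _random_configuration(rng)
            rep = compute_metrics(preds, sets).as_dict()
            oracle = recount_oracle(preds, sets)
            for k, v in oracle.items():
                if np.isnan(v):
                    assert np.isnan(rep[k]), k
                else:
                    assert rep[k] == pytest.approx(v), k

    def test_epoch_sensitivity_never_exceeds_seizure_sensitivity(self):
        # detecting an event needs only one detected epoch inside it, so a
        # trained detector's event-level sensitivity dominates its
        # epoch-level sensitivity; checked on leave-one-record-out outputs
        for seed in range(5):
            rng = np.random.default_rng(seed)
            sets = []
            for r in range(3):
                labels = [N] * 10 + [S] * 4 + [N] * 6
                events = [SeizureEvent(40.0, 56.0)]
                # moderate noise so some seizure epochs are missed
                base = np.array([1.5 if lab == S else 0.0 for lab in labels])
                x = base[:, None] + 1.0 * rng.standard_normal((20, 3))
                sets.append(_set(labels, events, record_id=f"r{r}",
                                 features=x))
            preds = loro_cv(sets)
            rep = compute_metrics(preds, sets)
            assert rep.total_events == 3
            assert rep.epoch_sensitivity <= rep.seizure_sensitivity + 1e-9
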
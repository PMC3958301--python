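"""SVM seizure classification, leave-one-record-out CV, and event metrics.

A soft-margin SVM with a second-order polynomial kernel classifies each
epoch's concatenated per-channel feature vector as seizure or non-seizure.
Features are z-scored with statistics from the training split only.
Evaluation is per subject with leave-one-record-out cross-validation:
every record is withheld once and predicted by a model trained on the
subject's remaining records.

Five metrics summarize performance:

* seizure sensitivity — % of annotated events with at least one
  correctly labeled seizure epoch;
* epoch sensitivity — % of seizure epochs labeled seizure;
* specificity — % of non-seizure epochs labeled non-seizure;
* FPR — falsely detected seizure epochs per hour of non-seizure time;
* latency — mean delay from event onset to the end of the first
  correctly labeled seizure epoch inside the event (detected events only).

Epochs straddling an event boundary (MIXED) take part in neither training
nor scoring.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import EpochLabel
from .synthetic_eeg import SeizureEvent

__all__ = [
    "LabeledFeatureSet",
    "ClassifierSpec",
    "MetricsReport",
    "train",
    "predict",
    "loro_cv",
    "compute_metrics",
]


@dataclass
class LabeledFeatureSet:
    """Feature rows of one record, with labels and event annotations."""

    features: np.ndarray            # (n_epochs, n_channels)
    labels: np.ndarray              # EpochLabel per epoch
    record_id: str
    epoch_duration_s: float
    events: list[SeizureEvent] = field(default_factory=list)

    def __post_init__(self):
        if self.features.shape[0] != len(self.labels):
            raise ValueError("feature rows and labels must align")
        if self.epoch_duration_s <= 0:
            raise ValueError("epoch duration must be positive")

    @property
    def n_epochs(self) -> int:
        return self.features.shape[0]

    def epoch_start_s(self, i: int) -> float:
        return i * self.epoch_duration_s

    def scored_mask(self) -> np.ndarray:
        return np.array([lab != EpochLabel.MIXED for lab in self.labels])


@dataclass(frozen=True)
class ClassifierSpec:
    """SVM settings; the kernel degree is fixed at 2."""

    c: float = 1.0
    class_weight: str | None = "balanced"
    standardize: bool = True
    gamma: str | float = "scale"
    coef0: float = 1.0

    @property
    def degree(self) -> int:
        return 2


@dataclass
class MetricsReport:
    seizure_sensitivity: float      # %
    epoch_sensitivity: float        # %  (nan if no seizure epochs)
    specificity: float              # %  (nan if no non-seizure epochs)
    fpr_per_hour: float             # nan if no non-seizure epochs
    mean_latency_s: float           # nan if no event detected
    tp_epochs: int = 0
    fp_epochs: int = 0
    tn_epochs: int = 0
    fn_epochs: int = 0
    detected_events: int = 0
    total_events: int = 0

    def as_dict(self) -> dict[str, float]:
        return {
            "seizure_sensitivity": self.seizure_sensitivity,
            "epoch_sensitivity": self.epoch_sensitivity,
            "specificity": self.specificity,
            "fpr_per_hour": self.fpr_per_hour,
            "mean_latency_s": self.mean_latency_s,
        }


def _build_model(spec: ClassifierSpec) -> Pipeline:
    steps = []
    if spec.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel="poly", degree=spec.degree, C=spec.c,
                             gamma=spec.gamma, coef0=spec.coef0,
                             class_weight=spec.class_weight)))
    return Pipeline(steps)


def train(features: np.ndarray, labels: np.ndarray,
          spec: ClassifierSpec | None = None) -> Pipeline:
    """Fit the epoch classifier on binary labels (1 = seizure).

    ``labels`` may be EpochLabel values or 0/1 integers; MIXED epochs must
    already be excluded.  A single-class training set raises.
    """
    spec = spec or ClassifierSpec()
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    model = _build_model(spec)
    model.fit(np.asarray(features, dtype=float), y)
    return model


def predict(model: Pipeline, features: np.ndarray) -> np.ndarray:
    """Predict 0/1 epoch labels with training-split standardization."""
    return model.predict(np.asarray(features, dtype=float)).astype(int)


def _binary_labels(labels) -> np.ndarray:
    out = []
    for lab in labels:
        if isinstance(lab, EpochLabel):
            if lab == EpochLabel.MIXED:
                raise ValueError("MIXED epochs must be excluded before training")
            out.append(1 if lab == EpochLabel.SEIZURE else 0)
        else:
            out.append(int(lab))
    return np.asarray(out, dtype=int)


def loro_cv(record_sets: list[LabeledFeatureSet],
            spec: ClassifierSpec | None = None
            ) -> list[np.ndarray | None]:
    """Leave-one-record-out predictions for one subject.

    Returns one prediction array per record (aligned with the input
    order, all epochs including MIXED — MIXED rows are predicted but must
    be masked out when scoring).  Folds whose training split contains a
    single class are skipped with a warning and yield ``None``.
    """
    if len(record_sets) < 2:
        raise ValueError("leave-one-record-out needs at least two records")
    spec = spec or ClassifierSpec()
    preds: list[np.ndarray | None] = []
    for i, test in enumerate(record_sets):
        xs, ys = [], []
        for j, rs in enumerate(record_sets):
            if j == i:
                continue
            mask = rs.scored_mask()
            xs.append(rs.features[mask])
            ys.append(_binary_labels(np.asarray(rs.labels, dtype=object)[mask]))
        x_tr = np.vstack(xs)
        y_tr = np.concatenate(ys)
        if len(np.unique(y_tr)) < 2:
            warnings.warn(
                f"fold {i} ({test.record_id}): single-class training split, "
                "skipped")
            preds.append(None)
            continue
        model = train(x_tr, y_tr, spec)
        preds.append(predict(model, test.features))
    return preds


def compute_metrics(predictions: list[np.ndarray | None],
                    record_sets: list[LabeledFeatureSet]) -> MetricsReport:
    """Score pooled predictions against labels and event annotations.

    MIXED epochs are excluded from every count.  FPR is normalized by
    non-seizure recording time (non-seizure epoch count × epoch duration),
    and latency is averaged over detected events only.
    """
    tp = fp = tn = fn = 0
    detected = 0
    total_events = 0
    latencies: list[float] = []
    for pred, rs in zip(predictions, record_sets):
        total_events += len(rs.events)
        if pred is None:
            continue
        if len(pred) != rs.n_epochs:
            raise ValueError("predictions misaligned with record epochs")
        for i in range(rs.n_epochs):
            lab = rs.labels[i]
            if lab == EpochLabel.MIXED:
                continue
            p = int(pred[i])
            if lab == EpochLabel.SEIZURE:
                tp += p
                fn += 1 - p
            else:
                fp += p
                tn += 1 - p
        for ev in rs.events:
            hit_end = None
            for i in range(rs.n_epochs):
                if rs.labels[i] != EpochLabel.SEIZURE or not pred[i]:
                    continue
                start = rs.epoch_start_s(i)
                end = start + rs.epoch_duration_s
                if start >= ev.onset_s - 1e-9 and end <= ev.offset_s + 1e-9:
                    hit_end = end
                    break
            if hit_end is not None:
                detected += 1
                latencies.append(hit_end - ev.onset_s)

    n_seiz = tp + fn
    n_non = fp + tn
    epoch_sens = 100.0 * tp / n_seiz if n_seiz else float("nan")
    specificity = 100.0 * tn / n_non if n_non else float("nan")
    seiz_sens = 100.0 * detected / total_events if total_events else float("nan")
    if n_non:
        hours = n_non * record_sets[0].epoch_duration_s / 3600.0
        fpr = fp / hours
    else:
        fpr = float("nan")
    latency = float(np.mean(latencies)) if latencies else float("nan")
    return MetricsReport(
        seizure_sensitivity=seiz_sens, epoch_sensitivity=epoch_sens,
        specificity=specificity, fpr_per_hour=fpr, mean_latency_s=latency,
        tp_epochs=tp, fp_epochs=fp, tn_epochs=tn, fn_epochs=fn,
        detected_events=detected, total_events=total_events)
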
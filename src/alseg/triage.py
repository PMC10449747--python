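"""Reference-free segmentation-quality triage and its evaluation.

In deployment a segmenter's output has no ground truth to score against,
so quality control needs a *reference-free* judgement.  The taxonomy used
here is a three-way triage of each predicted segmentation by the Dice score
it would achieve:

* ``POOR`` (Dice < 0.6) — an expert must re-segment from scratch;
* ``ADJUST`` (0.6 ≤ Dice < 0.8) — an expert checks and edits;
* ``ACCEPTABLE`` (Dice ≥ 0.8) — no review needed.

The cut-point boundaries are half-open by convention: 0.6 maps to ADJUST
and 0.8 maps to ACCEPTABLE, giving a total non-overlapping partition.

A triage *predictor* estimates the class from the case's images and the
segmenter's probability map alone.  :class:`TriagePredictorContract` pins
the surface; the shipped baseline is a multinomial logistic model on
confidence-style summary features of the probability map
(:func:`baseline_triage_features`).  Evaluation mirrors standard
multi-class practice: a 3×3 confusion matrix, one-vs-rest per-class
metrics, one-vs-rest ROC/AUC, and an escalation summary quantifying how
often errors still land in a class an expert would review anyway.

Note on specificity: the standard TN/(TN+FP) definition is used.  The
negative predictive value TN/(TN+FN) is also exposed, since published
quality-triage tables sometimes report that ratio under the specificity
heading.
"""

from __future__ import annotations

from abc import ABC, abstractmethod
from dataclasses import dataclass
from enum import IntEnum
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score

from .core import CaseBundle, VolumeGrid


class QualityClass(IntEnum):
    """Ordered three-way segmentation-quality taxonomy."""

    POOR = 0
    ADJUST = 1
    ACCEPTABLE = 2


QUALITY_LABELS = {
    QualityClass.POOR: "Poor Quality",
    QualityClass.ADJUST: "Acceptable with Adjustments",
    QualityClass.ACCEPTABLE: "Acceptable Quality",
}


@dataclass(frozen=True)
class TriageThresholds:
    """Dice cut-points separating the three quality classes."""

    lower: float = 0.6
    upper: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 < self.lower < self.upper < 1.0:
            raise ValueError(f"require 0 < lower < upper < 1, got {self.lower}, {self.upper}")


def bin_quality(dice_value: float, thresholds: TriageThresholds = TriageThresholds()) -> QualityClass:
    """Map a Dice score to its quality class (half-open boundary convention)."""
    if not 0.0 <= dice_value <= 1.0:
        raise ValueError(f"Dice value {dice_value} outside [0, 1]")
    if dice_value < thresholds.lower:
        return QualityClass.POOR
    if dice_value < thresholds.upper:
        return QualityClass.ADJUST
    return QualityClass.ACCEPTABLE


# ---------------------------------------------------------------------------
# Triage predictor contract and baseline


class NotFittedTriageError(RuntimeError):
    pass


class TriagePredictorContract(ABC):
    """Predicts a quality class from (case, probability map), no truth needed."""

    @abstractmethod
    def predict_class(
        self, case: CaseBundle, prob_map: VolumeGrid
    ) -> tuple[QualityClass, np.ndarray]:
        """Return (argmax class, per-class score triple summing to 1)."""


def baseline_triage_features(
    case: CaseBundle,
    prob_map: VolumeGrid,
    channels: Sequence[str] = ("T1c", "T2", "FLAIR"),
    decision_threshold: float = 0.5,
) -> np.ndarray:
    """Confidence-style summary features of a predicted segmentation.

    The intuition: a segmenter that is right tends to be *confident*
    (probabilities saturated near 0/1, little mass in the uncertain band)
    and its mask boundary tends to sit on image edges.  Features, in order:

    0. predicted foreground volume fraction,
    1. mean probability over predicted foreground (0 if empty),
    2. mean binary entropy of the probability map,
    3. uncertainty mass: fraction of voxels with probability in (0.3, 0.7),
    4. connected-component count of the thresholded mask,
    5+. per selected channel, mean image-gradient magnitude over boundary
        voxels of the mask (0 if the mask is empty).
    """
    p = np.asarray(prob_map.data, dtype=float)
    if p.size == 0:
        raise ValueError("empty probability map")
    mask = p >= decision_threshold
    vol_frac = float(mask.mean())
    mean_fg = float(p[mask].mean()) if mask.any() else 0.0
    eps = 1e-12
    pc = np.clip(p, eps, 1 - eps)
    entropy = float(np.mean(-pc * np.log(pc) - (1 - pc) * np.log(1 - pc)))
    uncertain = float(np.mean((p > 0.3) & (p < 0.7)))
    n_components = float(ndimage.label(mask)[1])
    feats = [vol_frac, mean_fg, entropy, uncertain, n_components]
    boundary = mask & ~ndimage.binary_erosion(mask, border_value=0) if mask.any() else None
    for name in channels:
        if name not in case.channels:
            continue
        if boundary is None or not boundary.any():
            feats.append(0.0)
            continue
        img = np.asarray(case.channels[name].data, dtype=float)
        grad = np.sqrt(sum(g ** 2 for g in np.gradient(img)))
        feats.append(float(grad[boundary].mean()))
    return np.asarray(feats, dtype=float)


class BaselineTriagePredictor(TriagePredictorContract):
    """Multinomial logistic triage predictor over baseline features."""

    def __init__(self, model: LogisticRegression, channels: Sequence[str]):
        self._model = model
        self._channels = tuple(channels)

    def predict_class(self, case, prob_map):
        feats = baseline_triage_features(case, prob_map, channels=self._channels)
        scores = self.predict_scores(feats)
        return QualityClass(int(np.argmax(scores))), scores

    def predict_scores(self, features: np.ndarray) -> np.ndarray:
        proba = self._model.predict_proba(features.reshape(1, -1))[0]
        scores = np.zeros(3)
        for cls, p in zip(self._model.classes_, proba):
            scores[int(cls)] = p
        return scores / scores.sum()


def fit_baseline_triage(
    labelled: Sequence[tuple[np.ndarray, QualityClass]],
    seed: int = 0,
    channels: Sequence[str] = ("T1c", "T2", "FLAIR"),
) -> BaselineTriagePredictor:
    """Fit the baseline triage predictor on (features, true class) pairs.

    The training pairs must come from cases *disjoint* from any pool the
    predictor will later score, to avoid information leakage.
    """
    if not labelled:
        raise ValueError("no labelled examples")
    X = np.vstack([f for f, _ in labelled])
    y = np.asarray([int(c) for _, c in labelled])
    if len(np.unique(y)) < 2:
        raise ValueError("triage training set contains a single class")
    model = LogisticRegression(max_iter=2000, random_state=seed, C=10.0)
    model.fit(X, y)
    return BaselineTriagePredictor(model, channels)


class OracleTriagePredictor(TriagePredictorContract):
    """Triage oracle: bins the *true* Dice of the thresholded probability map.

    Requires ground truth, so it is a test/benchmark device, not a
    deployable predictor; its one-hot scores make pipeline-equivalence
    checks exact.
    """

    def __init__(self, thresholds: TriageThresholds = TriageThresholds(), decision_threshold: float = 0.5):
        self.thresholds = thresholds
        self.decision_threshold = decision_threshold

    def predict_class(self, case, prob_map):
        from .core import merge_labels
        from .metrics import dice as _dice

        if case.truth_mask is None:
            raise ValueError(f"oracle triage needs ground truth for case {case.case_id!r}")
        truth = merge_labels(case.truth_mask) if case.multilabel else case.truth_mask
        pred = np.asarray(prob_map.data) >= self.decision_threshold
        cls = bin_quality(_dice(pred, truth.data), self.thresholds)
        scores = np.zeros(3)
        scores[int(cls)] = 1.0
        return cls, scores


# ---------------------------------------------------------------------------
# Evaluation


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3×3 confusion matrix; rows = true class, columns = predicted class."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        arr = np.asarray(self.counts, dtype=int)
        if arr.shape != (3, 3) or (arr < 0).any():
            raise ValueError("confusion matrix must be 3x3 with non-negative counts")
        object.__setattr__(self, "counts", arr)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def diagonal_total(self) -> int:
        return int(np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        names = [QUALITY_LABELS[QualityClass(i)] for i in range(3)]
        return pd.DataFrame(self.counts, index=names, columns=names)


def confusion_matrix(
    true_classes: Sequence[QualityClass],
    predicted_classes: Sequence[QualityClass],
) -> ConfusionMatrix3:
    """Tabulate true vs predicted quality classes."""
    if len(true_classes) != len(predicted_classes):
        raise ValueError("true/predicted length mismatch")
    counts = np.zeros((3, 3), dtype=int)
    for t, p in zip(true_classes, predicted_classes):
        counts[int(t), int(p)] += 1
    return ConfusionMatrix3(counts)


@dataclass(frozen=True)
class ClassMetrics:
    """One-vs-rest metrics for a single quality class."""

    target: QualityClass
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    f_score: float
    auc: Optional[float] = None


def _safe_ratio(num: int, denom: int) -> float:
    return num / denom if denom else float("nan")


def class_metrics(cm: ConfusionMatrix3, target: QualityClass) -> ClassMetrics:
    """One-vs-rest sensitivity, specificity, PPV, NPV and F-score for one class."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    t = int(target)
    tp = int(cm.counts[t, t])
    fn = int(cm.counts[t].sum()) - tp
    fp = int(cm.counts[:, t].sum()) - tp
    tn = cm.total - tp - fn - fp
    sens = _safe_ratio(tp, tp + fn)
    spec = _safe_ratio(tn, tn + fp)
    ppv = _safe_ratio(tp, tp + fp)
    npv = _safe_ratio(tn, tn + fn)
    if np.isnan(sens) or np.isnan(ppv) or (sens + ppv) == 0:
        f = float("nan")
    else:
        f = 2 * sens * ppv / (sens + ppv)
    return ClassMetrics(target=target, sensitivity=sens, specificity=spec, ppv=ppv, npv=npv, f_score=f)


def class_metrics_table(
    cm: ConfusionMatrix3,
    aucs: Optional[dict[QualityClass, float]] = None,
) -> pd.DataFrame:
    """Per-class metric table in the conventional column order."""
    rows = []
    for cls in QualityClass:
        m = class_metrics(cm, cls)
        rows.append(
            {
                "class": QUALITY_LABELS[cls],
                "n_cases": int(cm.counts[int(cls)].sum()),
                "sensitivity": m.sensitivity,
                "specificity": m.specificity,
                "ppv": m.ppv,
                "npv": m.npv,
                "f_score": m.f_score,
                "auc": (aucs or {}).get(cls, float("nan")),
            }
        )
    return pd.DataFrame(rows)


def roc_auc_ovr(
    true_classes: Sequence[QualityClass],
    score_triples: Sequence[Sequence[float]],
    target: QualityClass,
) -> float:
    """One-vs-rest ROC AUC using the target-class score (midpoint tie handling)."""
    y = np.asarray([int(c) == int(target) for c in true_classes])
    if y.all() or not y.any():
        raise ValueError("need both positive and negative examples of the target class")
    scores = np.asarray(score_triples, dtype=float)[:, int(target)]
    return float(roc_auc_score(y, scores))


@dataclass(frozen=True)
class EscalationSummary:
    """How safely the triage fails: errors that still reach an expert."""

    accuracy: float
    still_reviewed_among_misclassified: float  # NaN when nothing is misclassified
    safe_fraction: float  # correct, or misclassified into a still-reviewed class


def escalation_summary(cm: ConfusionMatrix3) -> EscalationSummary:
    """Accuracy plus the fractions of errors caught by expert review anyway.

    A misclassification is "still reviewed" when the *predicted* class is
    POOR or ADJUST — both route the case to an expert, so the error cannot
    silently ship a bad segmentation.
    """
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    correct = cm.diagonal_total
    mis = cm.total - correct
    off_diag = cm.counts.copy()
    np.fill_diagonal(off_diag, 0)
    reviewed_mis = int(off_diag[:, [int(QualityClass.POOR), int(QualityClass.ADJUST)]].sum())
    return EscalationSummary(
        accuracy=correct / cm.total,
        still_reviewed_among_misclassified=_safe_ratio(reviewed_mis, mis),
        safe_fraction=(correct + reviewed_mis) / cm.total,
    )
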
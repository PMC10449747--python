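"""Staged active-learning orchestration with Dice-threshold label substitution.

The scheme: train a segmenter on a small initial set of expert-labelled
cases, let it predict the remaining unlabelled pool in batches, and decide
per pool case whether the *model's own prediction* is good enough to train
on.  Cases the model handles well are added with the predicted mask
(costing no expert time); cases it struggles with are added with the
expert's ground truth.  Two decision modes exist:

* ``ORACLE`` — score each pool prediction by its true Dice against ground
  truth and substitute the prediction when Dice ≥ τ (proof-of-concept
  setting; τ defaults to 0.7, the conventional "good overlap" cut);
* ``TRIAGE`` — in deployment there is no ground truth to score against, so
  a reference-free quality predictor classes each prediction and only
  ``ACCEPTABLE`` cases keep the predicted mask.  Ground truth is consulted
  *only* for cases routed to expert labelling (emulating an expert
  segmenting on demand) and for post-hoc evaluation; every truth access is
  recorded in an audit trail so this constraint is machine-checkable.

Between rounds, training resumes from the checkpoint where validation
performance first plateaued rather than the latest epoch, so performance
changes are attributable to the new data rather than extra training time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Mapping, Optional, Sequence

import numpy as np

from .core import CaseBundle, merge_labels
from .metrics import dice, evaluate_case, summarize
from .segmenter import (
    MaskSource,
    SegmentationResult,
    SegmenterContract,
    TrainingHistory,
    TrainingRecord,
    ground_truth_record,
)
from .triage import QualityClass, TriagePredictorContract, TriageThresholds

log = logging.getLogger(__name__)


class ALMode(str, Enum):
    ORACLE = "oracle"
    TRIAGE = "triage"


@dataclass(frozen=True)
class RoundPlan:
    """How many cases to start with and how the pool is consumed per round."""

    initial_n: int
    increments: tuple[int, ...]
    mode: ALMode = ALMode.ORACLE
    oracle_threshold: float = 0.7
    thresholds: TriageThresholds = TriageThresholds()

    def __post_init__(self) -> None:
        if self.initial_n <= 0:
            raise ValueError("initial_n must be positive")
        if any(i <= 0 for i in self.increments):
            raise ValueError("increments must be positive")
        if not 0.0 < self.oracle_threshold < 1.0:
            raise ValueError("oracle threshold must lie in (0, 1)")

    @property
    def total_n(self) -> int:
        return self.initial_n + sum(self.increments)


@dataclass(frozen=True)
class PoolDecision:
    """The substitution decision for one pool case in one round."""

    case_id: str
    dice: Optional[float]  # oracle mode (and triage post-hoc audit when available)
    quality_class: Optional[QualityClass]  # triage mode
    mask_source: MaskSource


@dataclass
class RoundOutcome:
    """Everything recorded about one active-learning round."""

    round_index: int
    decisions: list[PoolDecision]
    n_ground_truth: int
    n_prediction: int
    training_set_size: int
    plateau_epoch: Optional[int]
    history: TrainingHistory
    test_summary: dict[str, float]


@dataclass
class TruthAccess:
    case_id: str
    purpose: str  # "training_label" | "evaluation" | "pool_scoring" | "triage_training"


@dataclass
class ExperimentResult:
    """Outcome of a full staged run: per-round logs plus the final record set."""

    outcomes: list[RoundOutcome]
    records: list[TrainingRecord]
    truth_audit: list[TruthAccess]

    @property
    def manual_burden(self) -> float:
        return manual_burden(self.records)


# ---------------------------------------------------------------------------
# Primitive operations


def detect_plateau(history: TrainingHistory, window: int = 5, epsilon: float = 0.005) -> int:
    """First epoch position whose trailing window has settled.

    Returns the smallest index ``e`` (into ``history.values``) such that the
    window ``values[e-window+1 .. e]`` has range ≤ ``epsilon`` and
    ``values[e] ≥ values[e-window+1] - epsilon`` (not sliding downhill).
    Falls through to the last epoch with a warning when no window
    qualifies.
    """
    n = len(history)
    if n < window:
        raise ValueError(f"history of length {n} shorter than window {window}")
    vals = history.values
    for e in range(window - 1, n):
        w = vals[e - window + 1 : e + 1]
        if max(w) - min(w) <= epsilon and vals[e] >= w[0] - epsilon:
            return e
    log.warning("no plateau found (window=%d, epsilon=%g); using final epoch", window, epsilon)
    return n - 1


def _truth_binary(case: CaseBundle):
    if case.truth_mask is None:
        raise ValueError(f"case {case.case_id!r} has no ground truth")
    truth = merge_labels(case.truth_mask) if case.multilabel else case.truth_mask
    return truth


def score_pool_oracle(
    model: SegmenterContract,
    pool: Sequence[CaseBundle],
    predictions: Optional[Mapping[str, SegmentationResult]] = None,
) -> dict[str, float]:
    """True Dice of the model's prediction per pool case (needs ground truth)."""
    scores: dict[str, float] = {}
    for case in pool:
        result = predictions[case.case_id] if predictions else model.predict(case)
        truth = _truth_binary(case)
        scores[case.case_id] = dice(result.mask.data, truth.data)
    return scores


def score_pool_triage(
    triage: TriagePredictorContract,
    model: SegmenterContract,
    pool: Sequence[CaseBundle],
    predictions: Optional[Mapping[str, SegmentationResult]] = None,
) -> dict[str, QualityClass]:
    """Reference-free quality class per pool case."""
    classes: dict[str, QualityClass] = {}
    for case in pool:
        result = predictions[case.case_id] if predictions else model.predict(case)
        cls, _scores = triage.predict_class(case, result.prob_map)
        classes[case.case_id] = cls
    return classes


def build_augmented_set(
    current: Sequence[TrainingRecord],
    pool_cases: Mapping[str, CaseBundle],
    predictions: Mapping[str, SegmentationResult],
    dice_scores: Optional[Mapping[str, float]] = None,
    quality_classes: Optional[Mapping[str, QualityClass]] = None,
    oracle_threshold: float = 0.7,
) -> tuple[list[TrainingRecord], list[PoolDecision]]:
    """Append one record per pool case, substituting labels by the rule.

    Oracle rule (``dice_scores`` given): the predicted mask replaces the
    ground truth iff Dice ≥ ``oracle_threshold``.  Triage rule
    (``quality_classes`` given): the predicted mask is kept iff the class
    is ACCEPTABLE; POOR and ADJUST route to ground truth.  Pool cases are
    appended in sorted case-id order for determinism.
    """
    if (dice_scores is None) == (quality_classes is None):
        raise ValueError("provide exactly one of dice_scores / quality_classes")
    existing = {r.case_id for r in current}
    out = list(current)
    decisions: list[PoolDecision] = []
    for case_id in sorted(pool_cases):
        if case_id in existing:
            raise ValueError(f"case {case_id!r} already in the training set")
        if case_id not in predictions:
            raise ValueError(f"no prediction for pool case {case_id!r}")
        case = pool_cases[case_id]
        if dice_scores is not None:
            score = dice_scores[case_id]
            use_prediction = score >= oracle_threshold
            cls = None
        else:
            cls = quality_classes[case_id]
            score = None
            use_prediction = cls == QualityClass.ACCEPTABLE
        if use_prediction:
            rec = TrainingRecord(
                case=case,
                label_mask=predictions[case_id].mask,
                mask_source=MaskSource.MODEL_PREDICTION,
            )
        else:
            rec = ground_truth_record(case)
        out.append(rec)
        decisions.append(
            PoolDecision(case_id=case_id, dice=score, quality_class=cls, mask_source=rec.mask_source)
        )
    return out, decisions


def manual_burden(records: Sequence[TrainingRecord]) -> float:
    """Fraction of training records whose label came from expert ground truth."""
    if not records:
        raise ValueError("no training records")
    n_gt = sum(1 for r in records if r.mask_source == MaskSource.GROUND_TRUTH)
    return n_gt / len(records)


# ---------------------------------------------------------------------------
# Full experiment


TriageFactory = Callable[[SegmenterContract, Sequence[CaseBundle], int], TriagePredictorContract]


@dataclass(frozen=True)
class ExperimentConfig:
    """Knobs of :func:`run_experiment` beyond the round plan itself."""

    epochs_initial: int = 12
    epochs_per_round: int = 6
    plateau_window: int = 5
    plateau_epsilon: float = 0.005
    use_plateau_checkpoint: bool = True


def run_experiment(
    cohort: Mapping[str, CaseBundle],
    train_ids: Sequence[str],
    pool_ids: Sequence[str],
    validation_ids: Sequence[str],
    test_ids: Sequence[str],
    plan: RoundPlan,
    segmenter_factory: Callable[[], SegmenterContract],
    triage_factory: Optional[TriageFactory] = None,
    triage_train_ids: Sequence[str] = (),
    seed: int = 0,
    config: ExperimentConfig = ExperimentConfig(),
) -> ExperimentResult:
    """Run a full staged active-learning experiment.

    The initial model is fitted on ``plan.initial_n`` ground-truth records
    drawn from ``train_ids``.  Each round then: rolls the model back to its
    validation-plateau checkpoint, draws the next pool batch (a seeded
    shuffle of ``pool_ids`` consumed in order, without replacement), scores
    the batch (oracle Dice or triage class), substitutes labels by the
    plan's rule, continues training on the union, and evaluates on the
    fixed test set — which stays constant across all rounds.

    In TRIAGE mode the predictor is built by ``triage_factory`` from the
    held-out ``triage_train_ids`` (disjoint from the pool, so the pool
    cannot leak into the predictor), and pool ground truth is touched only
    for cases the triage routes to expert labelling; the audit trail in the
    result records every access with its purpose.
    """
    if plan.mode == ALMode.TRIAGE and triage_factory is None:
        raise ValueError("TRIAGE mode requires a triage_factory")
    if plan.initial_n > len(train_ids):
        raise ValueError(f"initial_n={plan.initial_n} exceeds {len(train_ids)} train ids")
    if sum(plan.increments) > len(pool_ids):
        raise ValueError(f"plan increments need {sum(plan.increments)} pool cases, have {len(pool_ids)}")
    overlap = set(triage_train_ids) & set(pool_ids)
    if overlap:
        raise ValueError(f"triage training cases leak into the pool: {sorted(overlap)[:5]}")

    audit: list[TruthAccess] = []

    def take_truth(case_id: str, purpose: str) -> None:
        audit.append(TruthAccess(case_id=case_id, purpose=purpose))

    rng = np.random.default_rng(seed)
    pool_order = [pool_ids[i] for i in rng.permutation(len(pool_ids))]
    validation = [cohort[i] for i in validation_ids]
    for i in validation_ids:
        take_truth(i, "evaluation")

    records: list[TrainingRecord] = []
    for cid in list(train_ids)[: plan.initial_n]:
        records.append(ground_truth_record(cohort[cid]))
        take_truth(cid, "training_label")

    model = segmenter_factory()
    history = model.fit(records, validation, epochs=config.epochs_initial, seed=seed)

    triage: Optional[TriagePredictorContract] = None
    if plan.mode == ALMode.TRIAGE:
        triage_cases = [cohort[i] for i in triage_train_ids]
        for i in triage_train_ids:
            take_truth(i, "triage_training")
        triage = triage_factory(model, triage_cases, seed)

    def evaluate_test() -> dict[str, float]:
        reports = []
        for cid in test_ids:
            case = cohort[cid]
            result = model.predict(case)
            truth = _truth_binary(case)
            take_truth(cid, "evaluation")
            spacing = next(iter(case.channels.values())).spacing
            reports.append(evaluate_case(cid, result.mask.data, truth.data, spacing=spacing))
        return summarize(reports)

    outcomes: list[RoundOutcome] = [
        RoundOutcome(
            round_index=0,
            decisions=[],
            n_ground_truth=len(records),
            n_prediction=0,
            training_set_size=len(records),
            plateau_epoch=None,
            history=history.copy(),
            test_summary=evaluate_test(),
        )
    ]

    cursor = 0
    for round_index, batch_n in enumerate(plan.increments, start=1):
        plateau = None
        if config.use_plateau_checkpoint and len(history) >= config.plateau_window:
            plateau = detect_plateau(history, window=config.plateau_window, epsilon=config.plateau_epsilon)
            try:
                model.restore_epoch(history.epochs[plateau])
            except NotImplementedError:
                log.warning("segmenter does not support checkpoint restore; scoring with latest state")

        batch_ids = pool_order[cursor : cursor + batch_n]
        cursor += batch_n
        batch_cases = {cid: cohort[cid] for cid in batch_ids}
        predictions = {cid: model.predict(case) for cid, case in batch_cases.items()}

        if plan.mode == ALMode.ORACLE:
            for cid in batch_ids:
                take_truth(cid, "pool_scoring")
            scores = score_pool_oracle(model, list(batch_cases.values()), predictions)
            records, decisions = build_augmented_set(
                records, batch_cases, predictions,
                dice_scores=scores, oracle_threshold=plan.oracle_threshold,
            )
        else:
            classes = score_pool_triage(triage, model, list(batch_cases.values()), predictions)
            records, decisions = build_augmented_set(
                records, batch_cases, predictions, quality_classes=classes,
            )
        for d in decisions:
            if d.mask_source == MaskSource.GROUND_TRUTH:
                take_truth(d.case_id, "training_label")

        new_records = records[-len(batch_ids):] if batch_ids else []
        history = model.continue_fit(new_records, epochs=config.epochs_per_round, seed=seed + round_index)

        n_gt = sum(1 for d in decisions if d.mask_source == MaskSource.GROUND_TRUTH)
        outcomes.append(
            RoundOutcome(
                round_index=round_index,
                decisions=decisions,
                n_ground_truth=n_gt,
                n_prediction=len(decisions) - n_gt,
                training_set_size=len(records),
                plateau_epoch=None if plateau is None else history.epochs[plateau],
                history=history.copy(),
                test_summary=evaluate_test(),
            )
        )

    return ExperimentResult(outcomes=outcomes, records=records, truth_audit=audit)
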
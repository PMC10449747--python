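"""Plateau detection, pool scoring, label substitution and the staged loop."""

import numpy as np
import pytest

from alseg import active_learning as al
from alseg.core import merge_labels
from alseg.segmenter import MaskSource, TrainingHistory, ground_truth_record
from alseg.triage import OracleTriagePredictor, QualityClass, TriageThresholds

from .conftest import CannedSegmenter


def history_of(values):
    h = TrainingHistory()
    for e, v in enumerate(values):
        h.append(e, v)
    return h


class TestDetectPlateau:
    def test_hand_scanned_example(self):
        h = history_of([0.2, 0.5, 0.70, 0.71, 0.71, 0.72])
        assert al.detect_plateau(h, window=3, epsilon=0.02) == 4

    def test_constant_tail_first_full_window(self):
        h = history_of([0.0, 0.1, 0.25, 0.4, 0.5, 0.6, 0.6, 0.6, 0.6])
        assert al.detect_plateau(h, window=3, epsilon=0.0) == 7

    def test_never_plateauing_falls_through_to_last(self, caplog):
        h = history_of([0.1, 0.3, 0.5, 0.7, 0.9])
        with caplog.at_level("WARNING"):
            assert al.detect_plateau(h, window=3, epsilon=0.01) == 4
        assert any("no plateau" in r.message for r in caplog.records)

    def test_short_history_raises(self):
        with pytest.raises(ValueError):
            al.detect_plateau(history_of([0.1, 0.2]), window=3)

    def test_downhill_slide_not_a_plateau(self):
        # window range within epsilon but strictly decreasing below tolerance
        h = history_of([0.9, 0.85, 0.80, 0.75, 0.70])
        assert al.detect_plateau(h, window=3, epsilon=0.04) == 4  # falls through


class TestScorePool:
    def test_truth_echoing_mock_scores_all_ones(self, easy_cohort):
        mock = CannedSegmenter()
        mock.fit([ground_truth_record(easy_cohort[0])], [], epochs=1, seed=0)
        scores = al.score_pool_oracle(mock, easy_cohort[1:5])
        assert all(v == 1.0 for v in scores.values())

    def test_empty_mask_mock_scores_all_zero(self, easy_cohort):
        mock = CannedSegmenter(prob_fn=lambda case: np.zeros(case.shape))
        mock.fit([ground_truth_record(easy_cohort[0])], [], epochs=1, seed=0)
        scores = al.score_pool_oracle(mock, easy_cohort[1:5])
        assert all(v == 0.0 for v in scores.values())

    def test_missing_truth_raises(self, easy_cohort):
        from .conftest import make_case
        mock = CannedSegmenter(prob_fn=lambda case: np.zeros(case.shape))
        mock.fit([ground_truth_record(easy_cohort[0])], [], epochs=1, seed=0)
        no_truth = make_case("nt", shape=easy_cohort[0].shape, channels=("T1",))
        with pytest.raises(ValueError, match="no ground truth"):
            al.score_pool_oracle(mock, [no_truth])

    def test_triage_classes_match_oracle_binning(self, easy_cohort):
        mock = CannedSegmenter()
        mock.fit([ground_truth_record(easy_cohort[0])], [], epochs=1, seed=0)
        classes = al.score_pool_triage(OracleTriagePredictor(), mock, easy_cohort[1:5])
        dices = al.score_pool_oracle(mock, easy_cohort[1:5])
        from alseg.triage import bin_quality
        assert classes == {cid: bin_quality(d) for cid, d in dices.items()}


class TestBuildAugmentedSet:
    def _setup(self, easy_cohort, n=4):
        mock = CannedSegmenter()
        mock.fit([ground_truth_record(easy_cohort[0])], [], epochs=1, seed=0)
        pool = {c.case_id: c for c in easy_cohort[1 : 1 + n]}
        preds = {cid: mock.predict(c) for cid, c in pool.items()}
        current = [ground_truth_record(easy_cohort[0])]
        return current, pool, preds

    def test_dice_just_below_threshold_routes_to_ground_truth(self, easy_cohort):
        current, pool, preds = self._setup(easy_cohort, n=2)
        ids = sorted(pool)
        scores = {ids[0]: 0.69, ids[1]: 0.71}
        out, decisions = al.build_augmented_set(current, pool, preds, dice_scores=scores, oracle_threshold=0.7)
        by_id = {d.case_id: d.mask_source for d in decisions}
        assert by_id[ids[0]] == MaskSource.GROUND_TRUTH
        assert by_id[ids[1]] == MaskSource.MODEL_PREDICTION
        assert len(out) == len(current) + 2

    def test_triage_classes_route_only_acceptable_to_prediction(self, easy_cohort):
        current, pool, preds = self._setup(easy_cohort, n=3)
        ids = sorted(pool)
        classes = dict(zip(ids, [QualityClass.POOR, QualityClass.ADJUST, QualityClass.ACCEPTABLE]))
        _, decisions = al.build_augmented_set(current, pool, preds, quality_classes=classes)
        sources = [d.mask_source for d in sorted(decisions, key=lambda d: d.case_id)]
        assert sources == [MaskSource.GROUND_TRUTH, MaskSource.GROUND_TRUTH, MaskSource.MODEL_PREDICTION]

    def test_empty_pool_returns_current(self, easy_cohort):
        current, _, _ = self._setup(easy_cohort)
        out, decisions = al.build_augmented_set(current, {}, {}, dice_scores={})
        assert out == current and decisions == []

    def test_duplicate_case_raises(self, easy_cohort):
        current, pool, preds = self._setup(easy_cohort, n=1)
        dup_id = current[0].case_id
        existing_pred = next(iter(preds.values()))
        pool[dup_id] = current[0].case
        preds[dup_id] = existing_pred
        with pytest.raises(ValueError, match="already in the training set"):
            al.build_augmented_set(current, pool, preds, dice_scores={cid: 1.0 for cid in pool})

    def test_missing_prediction_raises(self, easy_cohort):
        current, pool, _ = self._setup(easy_cohort, n=2)
        with pytest.raises(ValueError, match="no prediction"):
            al.build_augmented_set(current, pool, {}, dice_scores={cid: 1.0 for cid in pool})

    def test_exactly_one_rule_must_be_given(self, easy_cohort):
        current, pool, preds = self._setup(easy_cohort, n=1)
        with pytest.raises(ValueError):
            al.build_augmented_set(current, pool, preds)


class TestManualBurden:
    def test_all_ground_truth(self, easy_cohort):
        recs = [ground_truth_record(c) for c in easy_cohort[:4]]
        assert al.manual_burden(recs) == 1.0

    def test_counting(self, easy_cohort):
        recs = [ground_truth_record(c) for c in easy_cohort[:10]]
        pred_recs = []
        for r in recs[3:]:
            pred_recs.append(
                al.TrainingRecord(case=r.case, label_mask=r.label_mask, mask_source=MaskSource.MODEL_PREDICTION)
            )
        assert al.manual_burden(recs[:3] + pred_recs) == pytest.approx(0.3)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            al.manual_burden([])


class TestRunExperiment:
    def _ids(self, mixed_split):
        return dict(
            train_ids=mixed_split.train_ids,
            pool_ids=mixed_split.pool_ids,
            validation_ids=mixed_split.validation_ids,
            test_ids=mixed_split.test_ids,
        )

    def test_zero_increments_is_plain_training(self, mixed_cohort, mixed_split):
        plan = al.RoundPlan(initial_n=6, increments=())
        res = al.run_experiment(
            mixed_cohort, **self._ids(mixed_split), plan=plan,
            segmenter_factory=CannedSegmenter, seed=0,
            config=al.ExperimentConfig(epochs_initial=3),
        )
        assert len(res.outcomes) == 1
        assert res.outcomes[0].training_set_size == 6
        assert res.manual_burden == 1.0

    def test_perfect_mock_substitutes_every_pool_case(self, mixed_cohort, mixed_split):
        plan = al.RoundPlan(initial_n=6, increments=(8, 8), mode=al.ALMode.ORACLE)
        res = al.run_experiment(
            mixed_cohort, **self._ids(mixed_split), plan=plan,
            segmenter_factory=CannedSegmenter, seed=0,
            config=al.ExperimentConfig(epochs_initial=3, epochs_per_round=2),
        )
        for oc in res.outcomes[1:]:
            assert oc.n_ground_truth == 0
            assert oc.n_prediction == len(oc.decisions)
        assert res.manual_burden == pytest.approx(6 / 22)

    def test_conservation_across_rounds(self, mixed_cohort, mixed_split):
        plan = al.RoundPlan(initial_n=5, increments=(7, 9))
        res = al.run_experiment(
            mixed_cohort, **self._ids(mixed_split), plan=plan,
            segmenter_factory=CannedSegmenter, seed=1,
            config=al.ExperimentConfig(epochs_initial=3, epochs_per_round=2),
        )
        sizes = [oc.training_set_size for oc in res.outcomes]
        assert sizes == [5, 12, 21]
        ids = [r.case_id for r in res.records]
        assert len(ids) == len(set(ids)) == 21

    def test_triage_mode_requires_factory(self, mixed_cohort, mixed_split):
        plan = al.RoundPlan(initial_n=5, increments=(5,), mode=al.ALMode.TRIAGE)
        with pytest.raises(ValueError, match="triage_factory"):
            al.run_experiment(
                mixed_cohort, **self._ids(mixed_split), plan=plan,
                segmenter_factory=CannedSegmenter, seed=0,
            )

    def test_infeasible_plan_raises(self, mixed_cohort, mixed_split):
        plan = al.RoundPlan(initial_n=5, increments=(10_000,))
        with pytest.raises(ValueError, match="pool cases"):
            al.run_experiment(
                mixed_cohort, **self._ids(mixed_split), plan=plan,
                segmenter_factory=CannedSegmenter, seed=0,
            )

    def test_triage_training_pool_leak_rejected(self, mixed_cohort, mixed_split):
        plan = al.RoundPlan(initial_n=5, increments=(5,), mode=al.ALMode.TRIAGE)
        with pytest.raises(ValueError, match="leak"):
            al.run_experiment(
                mixed_cohort, **self._ids(mixed_split), plan=plan,
                segmenter_factory=CannedSegmenter,
                triage_factory=lambda m, c, s: OracleTriagePredictor(),
                triage_train_ids=mixed_split.pool_ids[:3], seed=0,
            )

    def test_truth_audit_never_touches_substituted_pool_labels(self, mixed_cohort, mixed_split):
        """In triage mode, ground truth of cases kept as MODEL_PREDICTION is
        consulted only for post-hoc evaluation, never as a training label."""
        plan = al.RoundPlan(initial_n=6, increments=(10,), mode=al.ALMode.TRIAGE)
        res = al.run_experiment(
            mixed_cohort, **self._ids(mixed_split), plan=plan,
            segmenter_factory=CannedSegmenter,
            triage_factory=lambda m, c, s: OracleTriagePredictor(), seed=0,
            config=al.ExperimentConfig(epochs_initial=3, epochs_per_round=2),
        )
        substituted = {
            d.case_id for oc in res.outcomes for d in oc.decisions
            if d.mask_source == MaskSource.MODEL_PREDICTION
        }
        assert substituted  # the perfect mock substitutes everything
        label_accesses = {a.case_id for a in res.truth_audit if a.purpose == "training_label"}
        assert not substituted & label_accesses
        # no oracle Dice scoring happened either (reference-free constraint)
        assert not any(a.purpose == "pool_scoring" for a in res.truth_audit)

    def test_decisions_consistent_with_rule(self, mixed_cohort, mixed_split):
        plan = al.RoundPlan(initial_n=5, increments=(8,), oracle_threshold=0.7)
        mock = CannedSegmenter  # perfect → all dice 1.0 → all substituted
        res = al.run_experiment(
            mixed_cohort, **self._ids(mixed_split), plan=plan,
            segmenter_factory=mock, seed=0,
            config=al.ExperimentConfig(epochs_initial=3, epochs_per_round=2),
        )
        for oc in res.outcomes[1:]:
            for d in oc.decisions:
                expected = MaskSource.MODEL_PREDICTION if d.dice >= 0.7 else MaskSource.GROUND_TRUTH
                assert d.mask_source == expected
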
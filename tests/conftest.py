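"""Shared fixtures: tiny phantom cohorts, mock segmenters, oracle helpers."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from alseg.core import CaseBundle, VolumeGrid, cohort_by_id, merge_labels, split_cohort
from alseg.phantom import PhantomConfig, generate_cohort, mixed_difficulty_config
from alseg.segmenter import (
    MaskSource,
    SegmentationResult,
    SegmenterContract,
    TrainingHistory,
    TrainingRecord,
)

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_case(case_id="case", shape=(8, 8, 6), channels=("T1",), truth=None, seed=0):
    rng = np.random.default_rng(seed)
    chans = {c: VolumeGrid(data=rng.random(shape)) for c in channels}
    t = None if truth is None else VolumeGrid(data=np.asarray(truth, dtype=np.int16))
    return CaseBundle(case_id=case_id, channels=chans, truth_mask=t)


class CannedSegmenter(SegmenterContract):
    """Contract-conforming mock returning pre-set probability maps.

    ``prob_fn(case) -> ndarray`` defines the output; the default echoes the
    case's own (merged) truth mask, i.e. a perfect segmenter.
    """

    def __init__(self, prob_fn=None, decision_threshold=0.5):
        self._prob_fn = prob_fn
        self.decision_threshold = decision_threshold
        self._fitted = False
        self._history = TrainingHistory()
        self._epoch = 0

    def fit(self, records, validation, epochs, seed):
        if not records:
            raise ValueError("empty record list")
        self._fitted = True
        for _ in range(epochs):
            self._history.append(self._epoch, 0.9)
            self._epoch += 1
        return self._history.copy()

    def continue_fit(self, additional_records, epochs, seed):
        if not self._fitted:
            raise RuntimeError("fit first")
        for _ in range(epochs):
            self._history.append(self._epoch, 0.9)
            self._epoch += 1
        return self._history.copy()

    def predict(self, case):
        if not self._fitted:
            raise RuntimeError("fit first")
        if self._prob_fn is not None:
            prob = np.asarray(self._prob_fn(case), dtype=float)
        else:
            prob = merge_labels(case.truth_mask).data.astype(float)
        mask = (prob >= self.decision_threshold).astype(np.uint8)
        spacing = next(iter(case.channels.values())).spacing
        return SegmentationResult(
            case_id=case.case_id,
            mask=VolumeGrid(data=mask, spacing=spacing),
            prob_map=VolumeGrid(data=prob, spacing=spacing),
            model_tag="canned",
        )


@pytest.fixture(scope="session")
def easy_cohort():
    """30 easy phantoms (difficulty 0.15)."""
    return generate_cohort(PhantomConfig(n_cases=30, difficulty=0.15, seed=11))


@pytest.fixture(scope="session")
def mixed_cohort():
    """The shipped mixed-difficulty preset, 78 cases, indexed by id."""
    return cohort_by_id(generate_cohort(mixed_difficulty_config(n_cases=78, seed=5)))


@pytest.fixture(scope="session")
def mixed_split(mixed_cohort):
    return split_cohort(sorted(mixed_cohort), test_n=12, validation_fraction=0.05,
                        seed=5, initial_train_n=10)


# ---------------------------------------------------------------------------
# Independent brute-force oracles (kept free of the implementation paths)


def brute_force_mhd(mask_a, mask_b, spacing=(1.0, 1.0, 1.0), boundary_fn=None):
    """All-pairs modified Hausdorff distance on (boundary) voxel sets."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if boundary_fn is not None:
        pa, pb = boundary_fn(a), boundary_fn(b)
    else:
        pa, pb = np.argwhere(a), np.argwhere(b)
    scale = np.asarray(spacing, dtype=float)
    pa = pa * scale
    pb = pb * scale
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(axis=2))
    return max(d.min(axis=1).mean(), d.min(axis=0).mean()), d.max()


def brute_force_auc(y_true, scores):
    """Pair-counting AUC: (concordant + 0.5 * ties) / (n_pos * n_neg)."""
    y = np.asarray(y_true, dtype=bool)
    s = np.asarray(scores, dtype=float)
    pos, neg = s[y], s[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("need both classes")
    total = 0.0
    for p in pos:
        total += np.sum(p > neg) + 0.5 * np.sum(p == neg)
    return total / (len(pos) * len(neg))
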
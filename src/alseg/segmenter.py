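"""Pluggable segmentation-model contract and a desk-scale reference model.

The active-learning loop only needs three things from a segmenter: fit on a
set of training records, continue fitting after the training set grows, and
predict a probability map for a case.  :class:`SegmenterContract` pins that
surface down so a GPU CNN backend and the shipped reference model are
interchangeable.

The reference model, :class:`ReferenceVoxelSegmenter`, is a per-voxel
logistic classifier on hand-crafted features (channel intensities,
Gaussian-smoothed intensities at two scales, normalized spatial
coordinates) trained incrementally by SGD, one pass over the training set
per epoch.  It is intentionally simple: the point is that the surrounding
loop — plateau detection, pool scoring, label substitution, continued
training — is exercised end-to-end on a single CPU in seconds.  Background
voxels are subsampled (default 3:1 background:foreground) because lesions
occupy a small fraction of a brain volume.

Per-epoch snapshots of the classifier state make it possible to roll the
model back to a plateau epoch before scoring the pool, so later performance
changes are attributable to the data and not to extra training time.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage
from sklearn.linear_model import SGDClassifier

from .core import CaseBundle, VolumeGrid, merge_labels
from .metrics import dice

STATE_FORMAT_VERSION = 1


class MaskSource(str, Enum):
    """Provenance of the label mask used for training a case."""

    GROUND_TRUTH = "ground_truth"
    MODEL_PREDICTION = "model_prediction"


@dataclass(frozen=True)
class TrainingRecord:
    """A case paired with the binary mask actually used for training."""

    case: CaseBundle
    label_mask: VolumeGrid
    mask_source: MaskSource

    def __post_init__(self) -> None:
        if self.label_mask.shape != self.case.shape:
            raise ValueError(
                f"case {self.case.case_id!r}: label shape {self.label_mask.shape} "
                f"!= channel shape {self.case.shape}"
            )

    @property
    def case_id(self) -> str:
        return self.case.case_id


def ground_truth_record(case: CaseBundle) -> TrainingRecord:
    """Build a whole-tumor GROUND_TRUTH record from a case's truth mask."""
    if case.truth_mask is None:
        raise ValueError(f"case {case.case_id!r} has no ground truth")
    mask = merge_labels(case.truth_mask) if case.multilabel else case.truth_mask
    return TrainingRecord(case=case, label_mask=mask, mask_source=MaskSource.GROUND_TRUTH)


@dataclass(frozen=True)
class SegmentationResult:
    """Binary mask plus the voxelwise foreground-probability map behind it."""

    case_id: str
    mask: VolumeGrid
    prob_map: VolumeGrid
    model_tag: str = ""

    def __post_init__(self) -> None:
        if self.mask.shape != self.prob_map.shape:
            raise ValueError("mask and probability map shapes differ")
        p = np.asarray(self.prob_map.data)
        if p.min() < -1e-9 or p.max() > 1 + 1e-9:
            raise ValueError("probability map values outside [0, 1]")


@dataclass
class TrainingHistory:
    """Epoch-indexed validation metric trace."""

    metric: str = "validation_dice"
    epochs: list[int] = field(default_factory=list)
    values: list[float] = field(default_factory=list)

    def append(self, epoch: int, value: float) -> None:
        if self.epochs and epoch <= self.epochs[-1]:
            raise ValueError("epochs must be strictly increasing")
        self.epochs.append(int(epoch))
        self.values.append(float(value))

    def truncate(self, last_epoch: int) -> None:
        keep = [i for i, e in enumerate(self.epochs) if e <= last_epoch]
        n = len(keep)
        self.epochs = self.epochs[:n]
        self.values = self.values[:n]

    def copy(self) -> "TrainingHistory":
        return TrainingHistory(self.metric, list(self.epochs), list(self.values))

    def __len__(self) -> int:
        return len(self.epochs)


class SegmenterContract(ABC):
    """The surface the active-learning loop drives.

    Implementations must be deterministic given the seeds passed to
    :meth:`fit` / :meth:`continue_fit`.
    """

    @abstractmethod
    def fit(
        self,
        records: Sequence[TrainingRecord],
        validation: Sequence[CaseBundle],
        epochs: int,
        seed: int,
    ) -> TrainingHistory:
        """Train from scratch; returns the cumulative epoch-indexed history."""

    @abstractmethod
    def continue_fit(
        self,
        additional_records: Sequence[TrainingRecord],
        epochs: int,
        seed: int,
    ) -> TrainingHistory:
        """Resume training on the union of previous and additional records."""

    @abstractmethod
    def predict(self, case: CaseBundle) -> SegmentationResult:
        """Probability map plus thresholded mask for one case."""

    def restore_epoch(self, epoch: int) -> None:
        """Roll model state back to a checkpoint; optional capability."""
        raise NotImplementedError(f"{type(self).__name__} does not support checkpoint restore")


class NotFittedError(RuntimeError):
    pass


@dataclass(frozen=True)
class ReferenceSegmenterConfig:
    """Configuration of the reference voxel segmenter.

    ``deep_backend`` records the hyperparameters a GPU CNN adapter would
    use (batch size 40, initial learning rate 0.01, Adam, Dice loss with
    decay 1e-5, 64 epochs); they are carried as defaults for such an
    adapter and are not consumed by the reference model.
    """

    channels: tuple[str, ...] = ("T1", "T2", "FLAIR")
    smooth_sigmas: tuple[float, ...] = (1.0, 2.5)
    use_coordinates: bool = True
    decision_threshold: float = 0.5
    background_ratio: float = 3.0
    alpha: float = 1e-4
    deep_backend: dict = field(
        default_factory=lambda: {
            "batch_size": 40,
            "initial_learning_rate": 0.01,
            "optimizer": "adam",
            "loss": "dice",
            "decay": 1.0e-5,
            "epochs": 64,
        }
    )

    _KNOWN_FEATURES = ("intensity", "smoothed", "coordinates")


class ReferenceVoxelSegmenter(SegmenterContract):
    """Incremental per-voxel logistic segmenter on hand features."""

    def __init__(self, config: ReferenceSegmenterConfig = ReferenceSegmenterConfig()):
        self.config = config
        self._clf: Optional[SGDClassifier] = None
        self._records: list[TrainingRecord] = []
        self._validation: list[CaseBundle] = []
        self._history = TrainingHistory()
        self._snapshots: list[tuple[np.ndarray, np.ndarray, int]] = []
        self._feature_cache: dict[str, np.ndarray] = {}
        self._scaler: Optional[tuple[np.ndarray, np.ndarray]] = None
        self._next_epoch = 0

    # -- features ----------------------------------------------------------

    def extract_features(self, case: CaseBundle) -> np.ndarray:
        """Per-voxel feature matrix (n_voxels × n_features), cached per case."""
        cached = self._feature_cache.get(case.case_id)
        if cached is not None:
            return cached
        cols: list[np.ndarray] = []
        missing = [c for c in self.config.channels if c not in case.channels]
        if missing:
            raise ValueError(f"case {case.case_id!r} lacks channels {missing}")
        for name in self.config.channels:
            vol = np.asarray(case.channels[name].data, dtype=np.float32)
            cols.append(vol.ravel())
            for sigma in self.config.smooth_sigmas:
                cols.append(ndimage.gaussian_filter(vol, sigma=sigma).ravel())
        if self.config.use_coordinates:
            shape = case.shape
            grids = np.meshgrid(*(np.linspace(-1, 1, s, dtype=np.float32) for s in shape), indexing="ij")
            cols.extend(g.ravel() for g in grids)
        feats = np.column_stack(cols)
        self._feature_cache[case.case_id] = feats
        return feats

    def _training_arrays(self, records: Sequence[TrainingRecord], rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
        xs, ys = [], []
        for rec in records:
            feats = self.extract_features(rec.case)
            labels = np.asarray(rec.label_mask.data).ravel() > 0
            fg = np.nonzero(labels)[0]
            bg = np.nonzero(~labels)[0]
            n_bg = min(len(bg), max(int(self.config.background_ratio * max(len(fg), 1)), 256))
            bg_sel = rng.choice(bg, size=n_bg, replace=False) if len(bg) > n_bg else bg
            sel = np.concatenate([fg, bg_sel])
            xs.append(feats[sel])
            ys.append(labels[sel])
        X = np.vstack(xs)
        y = np.concatenate(ys)
        return X, y

    def _apply_scaler(self, X: np.ndarray) -> np.ndarray:
        mean, std = self._scaler
        return (X - mean) / std

    # -- training ----------------------------------------------------------

    def _run_epochs(self, records: Sequence[TrainingRecord], epochs: int, seed: int) -> None:
        rng = np.random.default_rng(seed)
        X, y = self._training_arrays(records, rng)
        if self._scaler is None:
            mean = X.mean(axis=0)
            std = X.std(axis=0)
            std[std < 1e-8] = 1.0
            self._scaler = (mean, std)
        X = self._apply_scaler(X)
        for _ in range(epochs):
            order = rng.permutation(len(y))
            self._clf.partial_fit(X[order], y[order], classes=np.array([False, True]))
            self._snapshots.append((self._clf.coef_.copy(), self._clf.intercept_.copy(), int(self._clf.t_)))
            val = self._validation_dice()
            self._history.append(self._next_epoch, val)
            self._next_epoch += 1

    def _validation_dice(self) -> float:
        if not self._validation:
            return float("nan")
        scores = []
        for case in self._validation:
            result = self.predict(case)
            truth = merge_labels(case.truth_mask) if case.multilabel else case.truth_mask
            scores.append(dice(result.mask.data, truth.data))
        return float(np.mean(scores))

    def fit(self, records, validation, epochs, seed) -> TrainingHistory:
        records = list(records)
        if not records:
            raise ValueError("cannot fit on an empty record list")
        self._records = records
        self._validation = list(validation)
        self._clf = SGDClassifier(
            loss="log_loss",
            alpha=self.config.alpha,
            learning_rate="optimal",
            random_state=seed,
            shuffle=False,
        )
        self._history = TrainingHistory()
        self._snapshots = []
        self._scaler = None
        self._next_epoch = 0
        self._run_epochs(records, epochs, seed)
        return self._history.copy()

    def continue_fit(self, additional_records, epochs, seed) -> TrainingHistory:
        if self._clf is None:
            raise NotFittedError("continue_fit called before fit")
        additional = list(additional_records)
        existing = {r.case_id for r in self._records}
        dup = [r.case_id for r in additional if r.case_id in existing]
        if dup:
            raise ValueError(f"cases already in the training set: {dup}")
        self._records = self._records + additional
        if epochs > 0:
            self._run_epochs(self._records, epochs, seed)
        return self._history.copy()

    def restore_epoch(self, epoch: int) -> None:
        if not self._snapshots:
            raise NotFittedError("no checkpoints to restore")
        if not 0 <= epoch < self._next_epoch:
            raise ValueError(f"epoch {epoch} outside [0, {self._next_epoch})")
        coef, intercept, t = self._snapshots[epoch]
        self._clf.coef_ = coef.copy()
        self._clf.intercept_ = intercept.copy()
        self._clf.t_ = t
        self._snapshots = self._snapshots[: epoch + 1]
        self._history.truncate(epoch)
        self._next_epoch = epoch + 1

    # -- inference ---------------------------------------------------------

    def predict(self, case: CaseBundle) -> SegmentationResult:
        if self._clf is None or not hasattr(self._clf, "coef_"):
            raise NotFittedError("predict called before fit")
        feats = self._apply_scaler(self.extract_features(case))
        prob = self._clf.predict_proba(feats)[:, 1].reshape(case.shape)
        mask = (prob >= self.config.decision_threshold).astype(np.uint8)
        spacing = next(iter(case.channels.values())).spacing
        return SegmentationResult(
            case_id=case.case_id,
            mask=VolumeGrid(data=mask, spacing=spacing),
            prob_map=VolumeGrid(data=prob, spacing=spacing),
            model_tag=f"reference@epoch{self._next_epoch - 1}",
        )

    # -- persistence -------------------------------------------------------

    def save(self, path: str | Path) -> None:
        """Serialize fitted model state to a single .npz file (versioned)."""
        if self._clf is None or not hasattr(self._clf, "coef_"):
            raise NotFittedError("nothing to save: model not fitted")
        meta = {
            "format_version": STATE_FORMAT_VERSION,
            "channels": list(self.config.channels),
            "smooth_sigmas": list(self.config.smooth_sigmas),
            "use_coordinates": self.config.use_coordinates,
            "decision_threshold": self.config.decision_threshold,
            "next_epoch": self._next_epoch,
        }
        np.savez(
            path,
            meta=json.dumps(meta),
            coef=self._clf.coef_,
            intercept=self._clf.intercept_,
            t=np.array([self._clf.t_]),
            scaler_mean=self._scaler[0],
            scaler_std=self._scaler[1],
        )

    @classmethod
    def load(cls, path: str | Path) -> "ReferenceVoxelSegmenter":
        with np.load(path, allow_pickle=False) as z:
            meta = json.loads(str(z["meta"]))
            if meta["format_version"] != STATE_FORMAT_VERSION:
                raise ValueError(f"unsupported model state version {meta['format_version']}")
            config = ReferenceSegmenterConfig(
                channels=tuple(meta["channels"]),
                smooth_sigmas=tuple(meta["smooth_sigmas"]),
                use_coordinates=bool(meta["use_coordinates"]),
                decision_threshold=float(meta["decision_threshold"]),
            )
            model = cls(config)
            model._clf = SGDClassifier(loss="log_loss", shuffle=False)
            model._clf.coef_ = z["coef"].copy()
            model._clf.intercept_ = z["intercept"].copy()
            model._clf.t_ = int(z["t"][0])
            model._clf.classes_ = np.array([False, True])
            model._scaler = (z["scaler_mean"].copy(), z["scaler_std"].copy())
            model._next_epoch = int(meta["next_epoch"])
        return model
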
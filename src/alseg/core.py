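"""Core domain types, NIfTI case I/O, label policy handling and cohort splitting.

The central container is :class:`CaseBundle`: one subject's co-registered
multi-parametric MR channels (any subset of T1, T1c, T2, FLAIR) plus an
optional integer ground-truth mask.  Masks may carry lesion sub-region
labels (necrotic core, edema, enhancing tumor in the common 1/2/4 dialect)
or a single whole-tumor label; :func:`merge_labels` collapses the former
into the latter.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

CHANNEL_NAMES = ("T1", "T1c", "T2", "FLAIR")


class ShapeMismatchError(ValueError):
    """Volumes expected on a common grid have different shapes."""


class LabelError(ValueError):
    """A label mask violates the active label policy."""


@dataclass(frozen=True)
class VolumeGrid:
    """A 3-D scalar volume on a regular grid.

    Parameters
    ----------
    data
        3-D array of finite scalars.
    spacing
        Physical voxel size per axis in mm (default isotropic 1 mm).
    affine
        Optional NIfTI affine, preserved on write; never used for
        resampling.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: Optional[np.ndarray] = field(default=None, compare=False)

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 3 or min(arr.shape) < 1:
            raise ValueError(f"expected a 3-D volume, got shape {arr.shape}")
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive values, got {self.spacing}")
        if np.issubdtype(arr.dtype, np.floating) and not np.all(np.isfinite(arr)):
            raise ValueError("volume contains NaN or Inf")
        object.__setattr__(self, "data", arr)
        object.__setattr__(self, "spacing", tuple(float(s) for s in self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def with_data(self, data: np.ndarray) -> "VolumeGrid":
        return replace(self, data=data)


@dataclass
class CaseBundle:
    """One subject: named channel volumes plus an optional truth mask."""

    case_id: str
    channels: dict[str, VolumeGrid]
    truth_mask: Optional[VolumeGrid] = None
    multilabel: bool = True

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError(f"case {self.case_id!r}: at least one channel required")
        shapes = {name: vol.shape for name, vol in self.channels.items()}
        ref = next(iter(shapes.values()))
        bad = {n: s for n, s in shapes.items() if s != ref}
        if bad:
            raise ShapeMismatchError(f"case {self.case_id!r}: channel shapes differ: {shapes}")
        if self.truth_mask is not None and self.truth_mask.shape != ref:
            raise ShapeMismatchError(
                f"case {self.case_id!r}: truth shape {self.truth_mask.shape} != channel shape {ref}"
            )

    @property
    def shape(self) -> tuple[int, int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def has_truth(self) -> bool:
        return self.truth_mask is not None


@dataclass(frozen=True)
class LabelPolicy:
    """Which integer codes count as tumor and how the union is encoded.

    The default sub-label set {1, 2, 4} covers the common necrotic-core /
    edema / enhancing-tumor dialect; the whole-tumor output code is 1.
    """

    sublabels: frozenset[int] = frozenset({1, 2, 4})
    wt_code: int = 1
    background_code: int = 0

    def __post_init__(self) -> None:
        if not self.sublabels:
            raise ValueError("sublabels must be non-empty")
        if self.background_code in self.sublabels:
            raise ValueError("background code cannot be a sublabel")
        if self.wt_code == self.background_code:
            raise ValueError("whole-tumor code must differ from background")


@dataclass(frozen=True)
class CohortSplit:
    """Disjoint ordered id lists for train / pool / validation / test."""

    train_ids: tuple[str, ...]
    pool_ids: tuple[str, ...]
    validation_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    def __post_init__(self) -> None:
        groups = (self.train_ids, self.pool_ids, self.validation_ids, self.test_ids)
        flat = [i for g in groups for i in g]
        if len(flat) != len(set(flat)):
            raise ValueError("split groups are not pairwise disjoint")

    @property
    def all_ids(self) -> tuple[str, ...]:
        return self.train_ids + self.pool_ids + self.validation_ids + self.test_ids

    def to_json(self, path: str | Path) -> None:
        payload = {
            "train_ids": list(self.train_ids),
            "pool_ids": list(self.pool_ids),
            "validation_ids": list(self.validation_ids),
            "test_ids": list(self.test_ids),
            "seed": self.seed,
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CohortSplit":
        payload = json.loads(Path(path).read_text())
        return cls(
            train_ids=tuple(payload["train_ids"]),
            pool_ids=tuple(payload["pool_ids"]),
            validation_ids=tuple(payload["validation_ids"]),
            test_ids=tuple(payload["test_ids"]),
            seed=int(payload["seed"]),
        )


# ---------------------------------------------------------------------------
# NIfTI I/O


def _load_nifti(path: str | Path) -> VolumeGrid:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    zooms = img.header.get_zooms()[:3]
    return VolumeGrid(data=data, spacing=tuple(float(z) for z in zooms), affine=np.asarray(img.affine))


def save_volume(volume: VolumeGrid, path: str | Path) -> None:
    """Write a volume as NIfTI, preserving affine when one is attached."""
    affine = volume.affine if volume.affine is not None else np.diag((*volume.spacing, 1.0))
    nib.save(nib.Nifti1Image(np.asarray(volume.data), affine), str(path))


def load_case(
    case_id: str,
    channel_paths: Mapping[str, str | Path],
    truth_path: Optional[str | Path] = None,
) -> CaseBundle:
    """Load one case from NIfTI files.

    All channels (and the truth mask, if given) must already share one voxel
    grid; a shape mismatch raises rather than silently resampling.  Truth
    masks must hold integer label values.
    """
    channels: dict[str, VolumeGrid] = {}
    for name, path in channel_paths.items():
        if not Path(path).exists():
            raise FileNotFoundError(f"case {case_id!r}: channel {name} missing at {path}")
        channels[name] = _load_nifti(path)
    truth = None
    if truth_path is not None:
        if not Path(truth_path).exists():
            raise FileNotFoundError(f"case {case_id!r}: truth mask missing at {truth_path}")
        truth = _load_nifti(truth_path)
        vals = np.asarray(truth.data)
        if not np.allclose(vals, np.round(vals)):
            raise LabelError(f"case {case_id!r}: truth mask contains non-integer labels")
        truth = truth.with_data(np.round(vals).astype(np.int16))
    return CaseBundle(case_id=case_id, channels=channels, truth_mask=truth)


def save_case(case: CaseBundle, out_dir: str | Path) -> dict[str, Path]:
    """Write every channel (and truth, if present) of a case as NIfTI files.

    Returns the mapping of written roles (channel name or ``"truth"``) to
    paths, suitable for manifest assembly.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}
    for name, vol in case.channels.items():
        p = out_dir / f"{case.case_id}_{name}.nii.gz"
        save_volume(vol, p)
        written[name] = p
    if case.truth_mask is not None:
        p = out_dir / f"{case.case_id}_seg.nii.gz"
        save_volume(case.truth_mask, p)
        written["truth"] = p
    return written


def write_manifest(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    """Write a cohort manifest CSV (columns: case_id, <channel> paths, truth)."""
    pd.DataFrame(rows).to_csv(path, index=False)


def load_manifest(path: str | Path) -> list[CaseBundle]:
    """Load every case listed in a manifest CSV.

    Relative paths in the manifest are resolved against the manifest's own
    directory so cohorts are relocatable.
    """
    path = Path(path)
    df = pd.read_csv(path)
    base = path.parent
    cases = []
    for _, row in df.iterrows():
        chans = {
            name: base / str(row[name])
            for name in CHANNEL_NAMES
            if name in df.columns and isinstance(row[name], str)
        }
        truth = None
        if "truth" in df.columns and isinstance(row["truth"], str):
            truth = base / str(row["truth"])
        cases.append(load_case(str(row["case_id"]), chans, truth))
    return cases


# ---------------------------------------------------------------------------
# Label policy


def merge_labels(
    mask: VolumeGrid,
    policy: LabelPolicy = LabelPolicy(),
    on_unknown: str = "error",
) -> VolumeGrid:
    """Collapse lesion sub-labels into a single whole-tumor label.

    Voxels whose code is in ``policy.sublabels`` become ``policy.wt_code``;
    everything else becomes background.  A nonzero code outside the policy
    raises by default (``on_unknown="error"``) or is treated as background
    with ``on_unknown="background"``.
    """
    data = np.asarray(mask.data)
    if not np.issubdtype(data.dtype, np.integer):
        if not np.allclose(data, np.round(data)):
            raise LabelError("mask contains non-integer values")
        data = np.round(data).astype(np.int16)
    codes = set(np.unique(data).tolist())
    unknown = codes - set(policy.sublabels) - {policy.background_code, policy.wt_code}
    # a mask already merged to {0, wt_code} passes through idempotently
    if policy.wt_code in codes and policy.wt_code not in policy.sublabels:
        pass
    if unknown:
        if on_unknown == "error":
            raise LabelError(f"mask contains codes outside the label policy: {sorted(unknown)}")
        if on_unknown != "background":
            raise ValueError(f"unknown on_unknown mode {on_unknown!r}")
    tumor = np.isin(data, sorted(set(policy.sublabels) | {policy.wt_code}))
    out = np.where(tumor, policy.wt_code, policy.background_code).astype(np.uint8)
    return mask.with_data(out)


# ---------------------------------------------------------------------------
# Cohort splitting


def split_cohort(
    ids: Sequence[str],
    test_n: int,
    validation_fraction: float = 0.08,
    seed: int = 0,
    initial_train_n: Optional[int] = None,
) -> CohortSplit:
    """Randomly partition case ids into test / validation / train (+ pool).

    ``test_n`` cases are held out first; of the remainder,
    ``floor(validation_fraction * n_remaining)`` become validation.  When
    ``initial_train_n`` is given, the non-validation remainder is further
    split into an initial training set of that size and an unlabeled pool
    for active learning; otherwise the pool is empty.  Deterministic given
    ``seed``.
    """
    ids = list(ids)
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate case ids")
    if not 0 <= validation_fraction < 1:
        raise ValueError("validation_fraction must be in [0, 1)")
    if test_n >= len(ids) or test_n < 0:
        raise ValueError(f"test_n={test_n} infeasible for {len(ids)} ids")
    rng = np.random.default_rng(seed)
    order = [ids[i] for i in rng.permutation(len(ids))]
    test = order[:test_n]
    rest = order[test_n:]
    val_n = int(np.floor(validation_fraction * len(rest)))
    validation = rest[:val_n]
    remainder = rest[val_n:]
    if initial_train_n is None:
        train, pool = remainder, []
    else:
        if initial_train_n > len(remainder):
            raise ValueError(f"initial_train_n={initial_train_n} exceeds {len(remainder)} available")
        train, pool = remainder[:initial_train_n], remainder[initial_train_n:]
    return CohortSplit(
        train_ids=tuple(train),
        pool_ids=tuple(pool),
        validation_ids=tuple(validation),
        test_ids=tuple(test),
        seed=seed,
    )


def cohort_by_id(cases: Iterable[CaseBundle]) -> dict[str, CaseBundle]:
    """Index a cohort by case_id, enforcing uniqueness."""
    out: dict[str, CaseBundle] = {}
    for c in cases:
        if c.case_id in out:
            raise ValueError(f"duplicate case_id {c.case_id!r} in cohort")
        out[c.case_id] = c
    return out
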
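"""Dataset-level crop-box computation and percentile intensity normalization.

The preprocessing recipe: take a maximum intensity projection (MIP) over
the whole cohort to find where any image has signal, derive one crop box
from it (optionally expanded to a fixed target size), crop every volume
with that box, and normalize each volume to [0, 1] by its 98th-percentile
intensity so a handful of bright outlier voxels cannot compress the
dynamic range.

Bias-field correction is deliberately an *external* pre-step: the pipeline
accepts already-corrected volumes and :func:`n4_hook_command` renders a
shell command for an external N4 tool; no correction is reimplemented here.
"""

from __future__ import annotations

import json
import shlex
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .core import CaseBundle, ShapeMismatchError, VolumeGrid

DEFAULT_TARGET_SIZE = (160, 216, 128)
DEFAULT_PERCENTILE = 98.0


@dataclass(frozen=True)
class CropBox:
    """An axis-aligned box: integer start offsets and extents per axis."""

    start: tuple[int, int, int]
    size: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s < 0 for s in self.start) or any(s <= 0 for s in self.size):
            raise ValueError(f"invalid crop box start={self.start} size={self.size}")

    @property
    def stop(self) -> tuple[int, int, int]:
        return tuple(a + b for a, b in zip(self.start, self.size))

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, a + b) for a, b in zip(self.start, self.size))

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({"start": list(self.start), "size": list(self.size)}) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "CropBox":
        d = json.loads(Path(path).read_text())
        return cls(start=tuple(d["start"]), size=tuple(d["size"]))


def dataset_mip(cohort: Iterable[CaseBundle], channel_selection: Optional[Sequence[str]] = None) -> VolumeGrid:
    """Elementwise maximum over every selected channel of every case."""
    acc: Optional[np.ndarray] = None
    spacing = (1.0, 1.0, 1.0)
    for case in cohort:
        names = channel_selection if channel_selection is not None else list(case.channels)
        for name in names:
            vol = case.channels[name]
            if acc is None:
                acc = np.asarray(vol.data, dtype=float).copy()
                spacing = vol.spacing
            else:
                if vol.shape != acc.shape:
                    raise ShapeMismatchError(f"case {case.case_id!r}: shape {vol.shape} != MIP shape {acc.shape}")
                np.maximum(acc, vol.data, out=acc)
    if acc is None:
        raise ValueError("empty cohort: nothing to project")
    return VolumeGrid(data=acc, spacing=spacing)


def crop_box_from_mip(
    mip: VolumeGrid,
    target_size: Optional[Sequence[int]] = None,
    threshold: float = 0.0,
) -> CropBox:
    """Derive a crop box from a dataset MIP.

    The box is the tight bounding box of voxels strictly above ``threshold``.
    If ``target_size`` is given the box is expanded symmetrically to exactly
    that size (odd padding goes to the lower-index side), then shifted to
    stay inside the grid.  The tight box exceeding the target on any axis
    is an error.
    """
    fg = np.asarray(mip.data) > threshold
    if not fg.any():
        raise ValueError("MIP has no voxel above the threshold: empty foreground")
    start, size = [], []
    for axis in range(3):
        other = tuple(a for a in range(3) if a != axis)
        profile = fg.any(axis=other)
        idx = np.nonzero(profile)[0]
        start.append(int(idx[0]))
        size.append(int(idx[-1] - idx[0] + 1))
    if target_size is None:
        return CropBox(start=tuple(start), size=tuple(size))
    target = tuple(int(t) for t in target_size)
    out_start = []
    for axis in range(3):
        tight_s, tight_n, t, dim = start[axis], size[axis], target[axis], fg.shape[axis]
        if tight_n > t:
            raise ValueError(f"axis {axis}: tight box size {tight_n} exceeds target {t}")
        if t > dim:
            raise ValueError(f"axis {axis}: target {t} exceeds grid size {dim}")
        pad = t - tight_n
        lo = tight_s - (pad + 1) // 2  # odd padding biased toward lower index
        lo = min(max(lo, 0), dim - t)
        out_start.append(int(lo))
    return CropBox(start=tuple(out_start), size=target)


def apply_crop(volume: VolumeGrid, box: CropBox) -> VolumeGrid:
    """Extract the box from a volume; spacing is unchanged."""
    if any(b > s for b, s in zip(box.stop, volume.shape)):
        raise ValueError(f"crop box {box} out of bounds for shape {volume.shape}")
    return volume.with_data(np.ascontiguousarray(volume.data[box.slices()]))


def crop_case(case: CaseBundle, box: CropBox) -> CaseBundle:
    """Apply one crop box to every channel and the truth mask of a case."""
    return CaseBundle(
        case_id=case.case_id,
        channels={n: apply_crop(v, box) for n, v in case.channels.items()},
        truth_mask=None if case.truth_mask is None else apply_crop(case.truth_mask, box),
        multilabel=case.multilabel,
    )


def normalize_p98(
    volume: VolumeGrid,
    percentile: float = DEFAULT_PERCENTILE,
    positive_only: bool = True,
) -> VolumeGrid:
    """Scale a volume into [0, 1] by its high-percentile intensity.

    The divisor is the ``percentile`` (default 98th) value of the strictly
    positive voxels — brain volumes are background-dominated, and including
    zeros would drag the percentile toward 0 — computed with the linear
    interpolation quantile convention.  Values above the divisor clip to 1.
    A volume with no positive voxels is returned clipped to [0, 1]
    unscaled (so an all-zero volume stays all-zero).
    """
    data = np.asarray(volume.data, dtype=float)
    sample = data[data > 0] if positive_only else data.ravel()
    if sample.size == 0:
        return volume.with_data(np.clip(data, 0.0, 1.0))
    p = float(np.percentile(sample, percentile))
    if p <= 0:
        return volume.with_data(np.clip(data, 0.0, 1.0))
    return volume.with_data(np.clip(data / p, 0.0, 1.0))


def normalize_case(case: CaseBundle, percentile: float = DEFAULT_PERCENTILE) -> CaseBundle:
    """Normalize every channel of a case; the truth mask is untouched."""
    return CaseBundle(
        case_id=case.case_id,
        channels={n: normalize_p98(v, percentile) for n, v in case.channels.items()},
        truth_mask=case.truth_mask,
        multilabel=case.multilabel,
    )


def n4_hook_command(template: str, in_path: str | Path, out_path: str | Path) -> list[str]:
    """Render a shell command for an external N4 bias-field correction tool.

    ``template`` uses ``{input}`` and ``{output}`` placeholders, e.g.
    ``"N4BiasFieldCorrection -i {input} -o {output}"``.  The command is
    returned as an argv list; running it is left to the caller.
    """
    rendered = template.format(input=str(in_path), output=str(out_path))
    return shlex.split(rendered)
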
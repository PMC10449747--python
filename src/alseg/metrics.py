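"""Per-case and cohort-level segmentation overlap and distance metrics.

Overlap metrics (Dice, Jaccard, sensitivity, positive predictive value) are
voxel-count ratios between a predicted and a ground-truth binary mask.  The
modified Hausdorff distance (MHD) follows the Dubuisson–Jain form: the
maximum of the two directed *mean* nearest-neighbour distances between the
masks' boundary voxel sets, which is far less sensitive to single outlier
voxels than the classical Hausdorff maximum.

Degenerate-input conventions, applied consistently throughout:

* both masks empty → Dice = Jaccard = 1.0 (perfect agreement on absence);
  exactly one empty → 0.0;
* sensitivity is NaN when the truth is empty, PPV is NaN when the
  prediction is empty (no positives to recover / no claims to verify);
* MHD is NaN when either mask is empty (no boundary to measure from).

NaNs are excluded (and counted) by :func:`summarize`.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.spatial import cKDTree

from .core import ShapeMismatchError

log = logging.getLogger(__name__)

METRIC_COLUMNS = ("sensitivity", "ppv", "dice", "jaccard", "mhd")


@dataclass(frozen=True)
class MetricReport:
    """All per-case metrics for one predicted segmentation."""

    case_id: str
    sensitivity: float
    ppv: float
    dice: float
    jaccard: float
    mhd: float

    def as_dict(self) -> dict[str, float | str]:
        return {
            "case_id": self.case_id,
            **{m: getattr(self, m) for m in METRIC_COLUMNS},
        }


def _as_bool(mask: np.ndarray) -> np.ndarray:
    return np.asarray(mask).astype(bool)


def _check_shapes(pred: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    p, t = _as_bool(pred), _as_bool(truth)
    if p.shape != t.shape:
        raise ShapeMismatchError(f"pred shape {p.shape} != truth shape {t.shape}")
    return p, t


def dice(pred, truth) -> float:
    """Dice similarity coefficient 2|P∩T| / (|P| + |T|)."""
    p, t = _check_shapes(pred, truth)
    denom = int(p.sum()) + int(t.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int(np.logical_and(p, t).sum()) / denom


def jaccard(pred, truth) -> float:
    """Jaccard similarity coefficient |P∩T| / |P∪T|."""
    p, t = _check_shapes(pred, truth)
    union = int(np.logical_or(p, t).sum())
    if union == 0:
        return 1.0
    return int(np.logical_and(p, t).sum()) / union


def sensitivity(pred, truth) -> float:
    """True-positive rate TP / (TP + FN); NaN when the truth is empty."""
    p, t = _check_shapes(pred, truth)
    nt = int(t.sum())
    if nt == 0:
        return float("nan")
    return int(np.logical_and(p, t).sum()) / nt


def ppv(pred, truth) -> float:
    """Positive predictive value TP / (TP + FP); NaN when the prediction is empty."""
    p, t = _check_shapes(pred, truth)
    npos = int(p.sum())
    if npos == 0:
        return float("nan")
    return int(np.logical_and(p, t).sum()) / npos


_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


def boundary_voxels(mask: np.ndarray) -> np.ndarray:
    """Coordinates (n×3) of boundary voxels: in the mask but 6-adjacent to outside."""
    m = _as_bool(mask)
    interior = ndimage.binary_erosion(m, structure=_FACE_STRUCT, border_value=0)
    return np.argwhere(m & ~interior)


def modified_hausdorff(
    pred,
    truth,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
    boundary: bool = True,
) -> float:
    """Modified Hausdorff distance between two masks.

    ``max(mean_a min_b d(a,b), mean_b min_a d(a,b))`` over the boundary
    voxel sets (or the full voxel sets with ``boundary=False``), with
    Euclidean distances scaled by ``spacing`` — so the result is in mm when
    spacing is physical, voxel units at the unit default.
    """
    p, t = _check_shapes(pred, truth)
    if not p.any() or not t.any():
        return float("nan")
    if boundary:
        pa, ta = boundary_voxels(p), boundary_voxels(t)
    else:
        pa, ta = np.argwhere(p), np.argwhere(t)
    scale = np.asarray(spacing, dtype=float)
    pa = pa * scale
    ta = ta * scale
    d_pt = cKDTree(ta).query(pa, k=1)[0]
    d_tp = cKDTree(pa).query(ta, k=1)[0]
    return float(max(d_pt.mean(), d_tp.mean()))


def evaluate_case(
    case_id: str,
    pred,
    truth,
    spacing: Sequence[float] = (1.0, 1.0, 1.0),
) -> MetricReport:
    """Compute the full metric panel for one case."""
    return MetricReport(
        case_id=case_id,
        sensitivity=sensitivity(pred, truth),
        ppv=ppv(pred, truth),
        dice=dice(pred, truth),
        jaccard=jaccard(pred, truth),
        mhd=modified_hausdorff(pred, truth, spacing=spacing),
    )


def summarize(reports: Iterable[MetricReport]) -> dict[str, float]:
    """Unweighted cohort means per metric, excluding undefined (NaN) values.

    The number of excluded cases per metric is logged and returned under
    ``<metric>_n_excluded`` keys alongside ``n_cases``.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no reports to summarize")
    out: dict[str, float] = {"n_cases": float(len(reports))}
    for m in METRIC_COLUMNS:
        vals = np.array([getattr(r, m) for r in reports], dtype=float)
        defined = vals[~np.isnan(vals)]
        n_excluded = int(np.isnan(vals).sum())
        if n_excluded:
            log.info("summarize: excluded %d undefined %s value(s)", n_excluded, m)
        out[m] = float(defined.mean()) if defined.size else float("nan")
        out[f"{m}_n_excluded"] = float(n_excluded)
    return out


def reports_to_frame(reports: Iterable[MetricReport]) -> pd.DataFrame:
    """One row per case, columns in the standard metric order."""
    return pd.DataFrame([r.as_dict() for r in reports], columns=("case_id", *METRIC_COLUMNS))
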
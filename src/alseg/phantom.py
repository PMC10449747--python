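"""Seeded generator of multi-channel brain phantoms with three-compartment lesions.

Each phantom case mimics the structure of a multi-parametric glioma MR
study: four co-registered channels (T1, T1c, T2, FLAIR) on one voxel grid,
an ellipsoidal "brain" of smoothly varying tissue intensity on a zero
background, and one or more lesions built as nested anisotropic ellipsoids
— a necrotic core (label 1) inside an enhancing rim (label 4) inside
peri-lesional edema (label 2), matching the common sub-label dialect so the
default label policy applies unchanged.  Channel contrast is
compartment-specific (e.g. edema is brightest on FLAIR, the rim enhances on
T1c) and additive Gaussian noise is applied per channel.

A single ``difficulty`` scalar in [0, 1] couples the knobs that make a
case hard for a segmenter — it scales lesion contrast down, noise up, and
adds distractor hyperintensities (small non-lesion bright blobs mimicking
white-matter lesions or artifacts) — so graded cohorts induce a monotone
performance trend.  A ``mixed`` preset draws a per-case difficulty from a
range, producing cohorts whose per-case Dice scores spread across quality
thresholds the way a real heterogeneous cohort does.

Everything is reproducible from ``(seed, case_index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage

from .core import CHANNEL_NAMES, CaseBundle, VolumeGrid, write_manifest, save_case

# Additive lesion contrast per channel and compartment, before difficulty
# scaling.  Signs follow the usual appearance: necrotic core dark on T1/T1c,
# bright on T2; rim enhancing on T1c; edema brightest on FLAIR/T2.
DEFAULT_CONTRAST: dict[str, dict[str, float]] = {
    "T1": {"core": -0.18, "rim": 0.05, "edema": -0.06},
    "T1c": {"core": -0.12, "rim": 0.38, "edema": 0.03},
    "T2": {"core": 0.32, "rim": 0.15, "edema": 0.26},
    "FLAIR": {"core": 0.10, "rim": 0.16, "edema": 0.36},
}

COMPARTMENT_CODES = {"core": 1, "edema": 2, "rim": 4}


@dataclass(frozen=True)
class PhantomConfig:
    """All knobs of the phantom cohort generator.

    ``difficulty`` d scales contrast by ``(1 - 0.9 d)``, noise by
    ``(1 + 3 d)``, and drives the expected number of lesion-mimicking
    distractor blobs (``6 d``); ``difficulty_range`` (when set) overrides
    it with a per-case uniform draw, giving a mixed-difficulty cohort.
    """

    shape: tuple[int, int, int] = (48, 48, 32)
    n_cases: int = 10
    channels: tuple[str, ...] = CHANNEL_NAMES
    lesion_count_range: tuple[int, int] = (1, 2)
    lesion_radius_range: tuple[float, float] = (4.0, 9.0)
    contrast: dict[str, dict[str, float]] = field(default_factory=lambda: {k: dict(v) for k, v in DEFAULT_CONTRAST.items()})
    noise_sd: float = 0.04
    difficulty: float = 0.3
    difficulty_range: Optional[tuple[float, float]] = None
    lesion_free_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.difficulty <= 1.0:
            raise ValueError("difficulty must lie in [0, 1]")
        if self.difficulty_range is not None:
            lo, hi = self.difficulty_range
            if not 0.0 <= lo <= hi <= 1.0:
                raise ValueError("difficulty_range must be within [0, 1]")
        if self.lesion_radius_range[0] <= 0:
            raise ValueError("lesion radii must be positive")
        if 2 * self.lesion_radius_range[1] >= min(self.shape):
            raise ValueError("lesion radius range does not fit inside the volume shape")
        if not 0.0 <= self.lesion_free_fraction <= 1.0:
            raise ValueError("lesion_free_fraction must lie in [0, 1]")
        unknown = set(self.channels) - set(self.contrast)
        if unknown:
            raise ValueError(f"no contrast defined for channels {sorted(unknown)}")


def mixed_difficulty_config(**overrides) -> PhantomConfig:
    """The shipped mixed-difficulty preset: per-case difficulty U(0.1, 0.9)."""
    params = dict(difficulty_range=(0.1, 0.9))
    params.update(overrides)
    return PhantomConfig(**params)


def _ellipsoid_mask(shape: Sequence[int], center: np.ndarray, radii: np.ndarray) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def _case_rng(seed: int, case_index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(case_index,)))


def generate_phantom_case(config: PhantomConfig, case_index: int) -> CaseBundle:
    """Generate one phantom case, bit-reproducible from (config.seed, case_index)."""
    rng = _case_rng(config.seed, case_index)
    shape = config.shape
    center = np.asarray(shape, dtype=float) / 2.0

    # ellipsoidal brain with a smooth low-frequency tissue texture
    brain_radii = np.asarray(shape, dtype=float) * 0.46
    brain = _ellipsoid_mask(shape, center, brain_radii)
    texture = ndimage.gaussian_filter(rng.normal(0.0, 1.0, size=shape), sigma=6.0)
    texture = 0.06 * texture / (np.abs(texture).max() + 1e-12)

    if config.difficulty_range is not None:
        difficulty = float(rng.uniform(*config.difficulty_range))
    else:
        difficulty = config.difficulty
    contrast_scale = 1.0 - 0.9 * difficulty
    noise_scale = 1.0 + 3.0 * difficulty

    labels = np.zeros(shape, dtype=np.uint8)
    lesion_free = rng.random() < config.lesion_free_fraction
    n_lesions = 0 if lesion_free else int(rng.integers(config.lesion_count_range[0], config.lesion_count_range[1] + 1))
    for _ in range(n_lesions):
        r_lo, r_hi = config.lesion_radius_range
        # anisotropic ("deformed") radii for the outer edema ellipsoid
        radii = rng.uniform(r_lo, r_hi, size=3)
        # keep the lesion inside the brain: center within the inner half
        offset = rng.uniform(-0.22, 0.22, size=3) * np.asarray(shape)
        c = center + offset
        c = np.clip(c, radii + 1, np.asarray(shape) - radii - 1)
        edema = _ellipsoid_mask(shape, c, radii) & brain
        rim = _ellipsoid_mask(shape, c, radii * 0.62) & brain
        core = _ellipsoid_mask(shape, c, radii * 0.34) & brain
        labels[edema] = COMPARTMENT_CODES["edema"]
        labels[rim] = COMPARTMENT_CODES["rim"]
        labels[core] = COMPARTMENT_CODES["core"]

    # distractor hyperintensities: small bright blobs that share the edema's
    # channel signature but are not lesion — they stress specificity
    distractor = np.zeros(shape, dtype=bool)
    n_distractors = int(rng.poisson(6.0 * difficulty))
    for _ in range(n_distractors):
        radii = rng.uniform(1.5, 3.5, size=3)
        c = center + rng.uniform(-0.3, 0.3, size=3) * np.asarray(shape)
        c = np.clip(c, radii + 1, np.asarray(shape) - radii - 1)
        distractor |= _ellipsoid_mask(shape, c, radii) & brain & (labels == 0)

    compartments = {
        name: labels == code for name, code in COMPARTMENT_CODES.items()
    }
    channels: dict[str, VolumeGrid] = {}
    for name in config.channels:
        vol = np.zeros(shape, dtype=float)
        vol[brain] = 0.45
        vol += np.where(brain, texture, 0.0)
        for comp, mask in compartments.items():
            vol[mask] += config.contrast[name][comp] * contrast_scale
        vol[distractor] += 0.8 * config.contrast[name]["edema"] * contrast_scale
        vol += rng.normal(0.0, config.noise_sd * noise_scale, size=shape)
        channels[name] = VolumeGrid(data=np.clip(vol, 0.0, 1.5))

    return CaseBundle(
        case_id=f"phantom_{case_index:04d}",
        channels=channels,
        truth_mask=VolumeGrid(data=labels),
        multilabel=True,
    )


def generate_cohort(config: PhantomConfig) -> list[CaseBundle]:
    """Generate the full in-memory phantom cohort."""
    if config.n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    return [generate_phantom_case(config, i) for i in range(config.n_cases)]


def write_cohort(config: PhantomConfig, out_dir: str | Path) -> Path:
    """Generate a cohort, write it as NIfTI files plus a CSV manifest.

    Returns the manifest path; the manifest round-trips through
    :func:`alseg.core.load_manifest`.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in generate_cohort(config):
        written = save_case(case, out_dir / case.case_id)
        row: dict[str, object] = {"case_id": case.case_id}
        for role, path in written.items():
            row[role] = str(path.relative_to(out_dir))
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
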
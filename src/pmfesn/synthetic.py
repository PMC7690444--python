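"""Synthetic imbalanced multi-parametric datasets with controllable separability.

Real acute-stroke cohorts of this kind are small (tens of cases), heavily
imbalanced across mRS grades, and access-restricted. This module emulates
their *structure* so the full pipeline — I/O, preprocessing, two-stage
balancing, pair construction, training, leave-one-out evaluation — can be
exercised end to end: each case is six aligned volumes sharing one lesion
geometry (mimicking co-registration), with a class-dependent lesion signal.

The lesion model is deliberately simple: a skull-stripped "brain" ellipsoid
with Gaussian intensity noise, plus a single lesion ellipsoid of random
centre and axes whose amplitude is ``effect_size * (1 + label)`` scaled by a
fixed signed per-modality contrast (diffusion/blood-volume maps drop in the
lesion, transit/delay maps rise). The amplitude is monotone in the label so
ordinal error metrics are meaningful. Nothing here models real perfusion
physics.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .io import MODALITIES, N_CLASSES, Dataset, StrokeCase

__all__ = ["SyntheticConfig", "generate_dataset", "separability_check", "write_dataset"]

# signed lesion contrast per modality: restricted diffusion and hypoperfusion
# lower ADC/CBV/CBF, lengthen transit/delay times
_CONTRAST = {
    "ADC": -1.0,
    "MTT": 1.2,
    "TTP": 1.1,
    "Tmax": 1.3,
    "CBV": -0.8,
    "CBF": -1.1,
}

# smooth baseline level inside the brain mask per modality
_BASELINE = {"ADC": 1.0, "MTT": 0.9, "TTP": 0.8, "Tmax": 0.7, "CBV": 1.1, "CBF": 1.2}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions of a synthetic cohort.

    Defaults emulate a 43-case cohort with heavy imbalance (majority class
    18, minority class 3) and a lesion signal five times the noise level.
    """

    class_counts: tuple = (4, 18, 11, 7, 3)
    volume_shape: tuple = (64, 64, 21)
    effect_size: float = 1.0
    noise_sd: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.class_counts) != N_CLASSES:
            raise ValueError(f"class_counts must have {N_CLASSES} entries")
        if any(c < 0 for c in self.class_counts):
            raise ValueError("class counts must be non-negative")
        if self.effect_size < 0 or self.noise_sd < 0:
            raise ValueError("effect_size and noise_sd must be non-negative")
        if len(self.volume_shape) != 3 or any(d < 3 for d in self.volume_shape):
            raise ValueError("volume_shape must be 3-D with all dims >= 3")


def _ellipsoid_mask(shape: Sequence[int], center: np.ndarray, semi: np.ndarray) -> np.ndarray:
    grids = np.meshgrid(*[np.arange(d, dtype=float) for d in shape], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return r2 <= 1.0


def generate_dataset(config: SyntheticConfig) -> Dataset:
    """Generate ``sum(class_counts)`` cases; identical config → identical data."""
    if sum(config.class_counts) == 0:
        raise ValueError("all class counts are zero; nothing to generate")
    rng = np.random.default_rng(config.seed)
    shape = np.asarray(config.volume_shape)
    brain = _ellipsoid_mask(shape, shape / 2.0, 0.45 * shape)
    cases = []
    idx = 0
    for label, count in enumerate(config.class_counts):
        for _ in range(count):
            # lesion centre jitter kept inside the brain ellipsoid and biased
            # toward the mid-axial band so the middle slices used by the
            # network always see lesion signal; size jitter stays below the
            # amplitude gap between adjacent classes so the class signal,
            # not lesion-volume variation, dominates mean-intensity features
            center = shape / 2.0 + rng.uniform(-0.12, 0.12, size=3) * shape
            scale = rng.uniform(0.97, 1.03)
            semi = scale * np.array([0.20, 0.20, 0.24]) * shape
            lesion = _ellipsoid_mask(shape, center, semi) & brain
            amplitude = config.effect_size * (1.0 + label)
            volumes = {}
            for mod in MODALITIES:
                vol = np.zeros(tuple(shape), dtype=np.float32)
                noise = rng.normal(0.0, config.noise_sd, size=tuple(shape))
                vol[brain] = _BASELINE[mod] + noise[brain]
                vol[lesion] += amplitude * _CONTRAST[mod]
                volumes[mod] = vol
            cases.append(StrokeCase(case_id=f"case_{idx:03d}", volumes=volumes, mrs=label))
            idx += 1
    return Dataset(cases=cases)


def separability_check(dataset: Dataset) -> float:
    """Leave-one-out nearest-centroid accuracy on per-modality mean intensities.

    A cheap, model-free gauge of how separable the generated classes are:
    each case is summarized by its six modality-mean intensities and
    classified by the nearest class centroid computed from all other cases.
    Monotone (in expectation) in ``effect_size``.
    """
    labels = np.array([c.mrs for c in dataset.cases])
    if len(np.unique(labels)) < 2:
        raise ValueError("separability requires at least two classes")
    feats = np.array(
        [[float(np.mean(c.volumes[m])) for m in MODALITIES] for c in dataset.cases]
    )
    hits = 0
    for i in range(len(labels)):
        mask = np.ones(len(labels), dtype=bool)
        mask[i] = False
        centroids, classes = [], []
        for m in np.unique(labels[mask]):
            classes.append(m)
            centroids.append(feats[mask & (labels == m)].mean(axis=0))
        d = np.linalg.norm(np.asarray(centroids) - feats[i], axis=1)
        if classes[int(np.argmin(d))] == labels[i]:
            hits += 1
    return hits / len(labels)


def write_dataset(dataset: Dataset, outdir: "str | Path") -> Path:
    """Write NIfTI volumes plus a CSV manifest; returns the manifest path.

    This routes synthetic data through the same on-disk layout as a real
    cohort so tests exercise the production I/O path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rows = []
    for case in dataset:
        row = {"case_id": case.case_id}
        for mod in MODALITIES:
            fname = f"{case.case_id}_{mod}.nii.gz"
            nib.save(nib.Nifti1Image(np.asarray(case.volumes[mod], dtype=np.float32), np.eye(4)), str(outdir / fname))
            row[mod.lower()] = fname
        row["mrs"] = case.mrs
        rows.append(row)
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
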
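"""Preprocessing: resize, middle-slice extraction, fold-wise mean centering.

Each case's six volumes are resampled to a common grid (default
150 x 150 x 21), and the three middle axial slices are stacked as the
channels of a 2-D network input per modality. Within every leave-one-out
fold the voxelwise mean image of the training slabs (originals plus
augmented — they are training data in the fold) is subtracted from both the
training and the held-out slabs; the held-out case never contributes to the
mean.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import map_coordinates

from .io import MODALITIES, StrokeCase

DEFAULT_TARGET = (150, 150, 21)

__all__ = [
    "DEFAULT_TARGET",
    "PreparedSample",
    "resize_volume",
    "extract_middle_slices",
    "prepare_case",
    "fold_mean_center",
]


@dataclass
class PreparedSample:
    """Fixed-size network input: one H x W x 3 slab per modality.

    ``provenance`` distinguishes original patients from augmentation
    products; only originals may serve as test-time reference samples.
    ``transform`` records the geometric transform that produced an augmented
    sample (None for originals).
    """

    case_id: str
    slabs: dict
    mrs: int
    provenance: str = "original"
    source_case_id: Optional[str] = None
    transform: object = None

    def __post_init__(self) -> None:
        if self.provenance not in ("original", "augmented"):
            raise ValueError(f"bad provenance {self.provenance!r}")
        if self.source_case_id is None:
            self.source_case_id = self.case_id
        if self.provenance == "original" and self.source_case_id != self.case_id:
            raise ValueError("original samples must be their own source")
        missing = [m for m in MODALITIES if m not in self.slabs]
        if missing:
            raise ValueError(f"sample {self.case_id!r}: missing slabs {missing}")
        shapes = {np.asarray(s).shape for s in self.slabs.values()}
        if len(shapes) != 1:
            raise ValueError(f"sample {self.case_id!r}: slabs have differing shapes {shapes}")
        shp = next(iter(shapes))
        if len(shp) != 3 or shp[2] != 3:
            raise ValueError(f"sample {self.case_id!r}: slabs must be H x W x 3, got {shp}")

    @property
    def slab_shape(self) -> tuple[int, int, int]:
        return np.asarray(self.slabs[MODALITIES[0]]).shape


def resize_volume(volume: np.ndarray, target: Sequence[int] = DEFAULT_TARGET) -> np.ndarray:
    """Trilinear, endpoint-aligned resampling to ``target`` shape.

    Separable linear interpolation with grid corners mapped to grid corners,
    so constants are preserved exactly and an identity-shaped input is
    returned unchanged (up to float arithmetic).
    """
    volume = np.asarray(volume, dtype=float)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    if any(d < 1 for d in volume.shape):
        raise ValueError("all input dims must be >= 1")
    target = tuple(int(t) for t in target)
    axes = [
        np.linspace(0, volume.shape[i] - 1, target[i]) if volume.shape[i] > 1 else np.zeros(target[i])
        for i in range(3)
    ]
    coords = np.meshgrid(*axes, indexing="ij")
    return map_coordinates(volume, np.stack(coords), order=1, mode="nearest")


def extract_middle_slices(volume: np.ndarray) -> np.ndarray:
    """Stack the three centered axial slices of a volume as channels.

    For depth D the slices are indices floor(D/2)-1, floor(D/2), floor(D/2)+1
    (9, 10, 11 for the standard 21-slice grid), in ascending depth order.
    """
    volume = np.asarray(volume)
    if volume.ndim != 3:
        raise ValueError(f"expected a 3-D volume, got shape {volume.shape}")
    depth = volume.shape[2]
    if depth < 3:
        raise ValueError(f"need depth >= 3 to extract middle slices, got {depth}")
    mid = depth // 2
    return volume[:, :, mid - 1 : mid + 2].copy()


def prepare_case(case: StrokeCase, target: Sequence[int] = DEFAULT_TARGET) -> PreparedSample:
    """Resize all six volumes and extract their middle slices.

    The same grid and indices are used for every modality, so the six slabs
    stay mutually registered. Pure function of the input voxel data.
    """
    slabs = {m: extract_middle_slices(resize_volume(case.volumes[m], target)) for m in MODALITIES}
    return PreparedSample(case_id=case.case_id, slabs=slabs, mrs=case.mrs)


def fold_mean_center(
    train: Sequence[PreparedSample], test: Optional[PreparedSample] = None
) -> tuple[list, Optional[PreparedSample]]:
    """Subtract the per-modality voxelwise training-mean slab from all slabs.

    The mean is an image (one value per voxel position and modality), taken
    over every training sample handed in — augmented samples included when
    present. Returns new samples; inputs are not modified.
    """
    train = list(train)
    if not train:
        raise ValueError("cannot center with an empty training set")
    means = {
        m: np.mean([np.asarray(s.slabs[m], dtype=float) for s in train], axis=0)
        for m in MODALITIES
    }

    def center(sample: PreparedSample) -> PreparedSample:
        return replace(
            sample,
            slabs={m: np.asarray(sample.slabs[m], dtype=float) - means[m] for m in MODALITIES},
        )

    return [center(s) for s in train], (center(test) if test is not None else None)
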
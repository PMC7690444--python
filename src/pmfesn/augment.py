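"""Stage-1 class balancing: geometric augmentation up to the largest class.

Every minority class is topped up with transformed copies of its own cases
until all classes match the largest class's count. One geometric transform
(zoom, rotation, translation, shear, horizontal/vertical flip) is drawn per
new sample and applied identically to all six modality slabs, preserving
their mutual registration. Only training data is ever augmented; the
held-out case never passes through this module.

Transform magnitudes are configurable; the defaults (rotation +/-10 deg,
zoom 0.9-1.1, translation +/-10%, shear +/-0.1, both flips allowed) are
conventional mild settings for skull-stripped brain slices. Pixels moved in
from outside the field of view are filled with 0, the background value of
skull-stripped images.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import affine_transform

from .io import MODALITIES
from .preprocess import PreparedSample

__all__ = [
    "AugmentationPolicy",
    "GeometricTransform",
    "largest_class",
    "sample_transform",
    "apply_transform",
    "augment_to_balance",
]


@dataclass(frozen=True)
class AugmentationPolicy:
    rotation_max_deg: float = 10.0
    zoom_range: tuple = (0.9, 1.1)
    translate_max_frac: float = 0.1
    shear_max: float = 0.1
    hflip: bool = True
    vflip: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rotation_max_deg < 0:
            raise ValueError("rotation_max_deg must be >= 0")
        lo, hi = self.zoom_range
        if not (0 < lo <= hi):
            raise ValueError("zoom_range must satisfy 0 < low <= high")
        if not (0 <= self.translate_max_frac <= 0.5):
            raise ValueError("translate_max_frac must be in [0, 0.5]")
        if self.shear_max < 0:
            raise ValueError("shear_max must be >= 0")


@dataclass(frozen=True)
class GeometricTransform:
    """One realized draw from a policy, shared across a sample's modalities."""

    rotation_deg: float = 0.0
    zoom: float = 1.0
    tx_frac: float = 0.0
    ty_frac: float = 0.0
    shear: float = 0.0
    hflip: bool = False
    vflip: bool = False

    @property
    def is_identity_affine(self) -> bool:
        return (
            self.rotation_deg == 0.0
            and self.zoom == 1.0
            and self.tx_frac == 0.0
            and self.ty_frac == 0.0
            and self.shear == 0.0
        )


def largest_class(counts: "dict | Sequence[int]") -> tuple[int, dict]:
    """Largest per-class count I and per-class deficits I - n_m."""
    if isinstance(counts, dict):
        items = dict(counts)
    else:
        items = {m: int(c) for m, c in enumerate(counts)}
    if not items or max(items.values()) < 1:
        raise ValueError("need at least one class with a positive count")
    big = max(items.values())
    return big, {m: big - n for m, n in items.items()}


def sample_transform(policy: AugmentationPolicy, rng: np.random.Generator) -> GeometricTransform:
    """Draw transform parameters uniformly within the policy bounds."""
    return GeometricTransform(
        rotation_deg=float(rng.uniform(-policy.rotation_max_deg, policy.rotation_max_deg)),
        zoom=float(rng.uniform(*policy.zoom_range)),
        tx_frac=float(rng.uniform(-policy.translate_max_frac, policy.translate_max_frac)),
        ty_frac=float(rng.uniform(-policy.translate_max_frac, policy.translate_max_frac)),
        shear=float(rng.uniform(-policy.shear_max, policy.shear_max)),
        hflip=bool(policy.hflip and rng.random() < 0.5),
        vflip=bool(policy.vflip and rng.random() < 0.5),
    )


def _affine_matrix(t: GeometricTransform) -> np.ndarray:
    """Forward in-plane mapping (row, col) -> (row', col') about the origin."""
    th = math.radians(t.rotation_deg)
    rot = np.array([[math.cos(th), -math.sin(th)], [math.sin(th), math.cos(th)]])
    shear = np.array([[1.0, t.shear], [0.0, 1.0]])
    return t.zoom * rot @ shear


def apply_transform(slab: np.ndarray, t: GeometricTransform) -> np.ndarray:
    """Apply one transform to an H x W x C slab (bilinear, zero fill).

    The affine part (rotation/zoom/shear about the slab centre, then
    translation by a fraction of the slab size) is skipped entirely when it
    is the identity, so pure flips move pixels exactly: a horizontal flip
    sends column x to W-1-x, a vertical flip sends row y to H-1-y.
    """
    slab = np.asarray(slab, dtype=float)
    if slab.ndim != 3:
        raise ValueError(f"expected H x W x C slab, got shape {slab.shape}")
    h, w = slab.shape[:2]
    out = slab
    if not t.is_identity_affine:
        fwd = _affine_matrix(t)
        inv = np.linalg.inv(fwd)
        center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
        shift = np.array([t.ty_frac * h, t.tx_frac * w])
        # affine_transform maps output coords to input coords:
        # in = inv @ (out - center - shift) + center
        offset = center - inv @ (center + shift)
        out = np.stack(
            [
                affine_transform(out[:, :, c], inv, offset=offset, order=1, mode="constant", cval=0.0)
                for c in range(out.shape[2])
            ],
            axis=2,
        )
    if t.hflip:
        out = out[:, ::-1, :]
    if t.vflip:
        out = out[::-1, :, :]
    return np.ascontiguousarray(out)


def augment_to_balance(
    train: Sequence[PreparedSample],
    policy: AugmentationPolicy,
    rng: Optional[np.random.Generator] = None,
    classes: Optional[Sequence[int]] = None,
) -> list:
    """Top every class up to the largest class's count with augmented samples.

    The input must consist of original samples only. For each class with
    deficit k, k new samples are created; source originals are cycled
    round-robin in a seeded-shuffled order, and each new sample applies one
    freshly drawn transform identically to all six modality slabs. An
    already-balanced input is returned unchanged (plus nothing).

    ``classes`` optionally fixes the class set to balance over; a listed
    class with no training sample cannot be augmented and raises.
    """
    train = list(train)
    bad = [s.case_id for s in train if s.provenance != "original"]
    if bad:
        raise ValueError(f"augmentation input must be originals only; got augmented {bad}")
    if rng is None:
        rng = np.random.default_rng(policy.seed)
    by_class: dict = {}
    for s in train:
        by_class.setdefault(s.mrs, []).append(s)
    if classes is not None:
        counts = {int(m): len(by_class.get(int(m), [])) for m in classes}
    else:
        counts = {m: len(v) for m, v in by_class.items()}
    big, deficits = largest_class(counts)
    out = list(train)
    for m in sorted(deficits):
        k = deficits[m]
        if k == 0:
            continue
        pool = by_class.get(m, [])
        if not pool:
            raise ValueError(f"class {m} has no sample to augment (largest class has {big})")
        order = list(rng.permutation(len(pool)))
        for j in range(k):
            src = pool[order[j % len(pool)]]
            t = sample_transform(policy, rng)
            slabs = {mod: apply_transform(src.slabs[mod], t) for mod in MODALITIES}
            out.append(
                replace(
                    src,
                    case_id=f"{src.case_id}__aug{j}",
                    slabs=slabs,
                    provenance="augmented",
                    source_case_id=src.case_id,
                    transform=t,
                )
            )
    return out
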
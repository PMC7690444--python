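"""Core data model and I/O for multi-parametric stroke MRI cases.

A case is six co-registered, skull-stripped 3-D parameter maps — ADC from
diffusion imaging plus five perfusion-derived maps (MTT, TTP, Tmax, CBV,
CBF) — with a 3-month clinical outcome label on the modified Rankin Scale
(mRS, here 0-4). Volumes are read from NIfTI; datasets are described by a
CSV manifest with one row per case.

Clinical covariates (time since stroke, time to treatment, TICI grade) are
carried on the case record for completeness but are never consumed by the
model.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

from .metrics import EvaluationReport

MODALITIES: tuple[str, ...] = ("ADC", "MTT", "TTP", "Tmax", "CBV", "CBF")
"""Canonical modality names, in the fixed order used throughout the package."""

N_CLASSES = 5  # mRS grades 0..4 in this cohort

__all__ = [
    "MODALITIES",
    "N_CLASSES",
    "ClinicalRecord",
    "StrokeCase",
    "Dataset",
    "load_case",
    "load_dataset",
    "write_report",
    "read_report",
]


@dataclass(frozen=True)
class ClinicalRecord:
    """Pre/post-treatment clinical covariates; parsed but unused by the model."""

    tss_minutes: Optional[float] = None
    ttt_minutes: Optional[float] = None
    tici_grade: Optional[str] = None


@dataclass
class StrokeCase:
    """Six aligned 3-D parameter maps plus the mRS outcome of one patient."""

    case_id: str
    volumes: dict
    mrs: int
    clinical: Optional[ClinicalRecord] = None

    def __post_init__(self) -> None:
        missing = [m for m in MODALITIES if m not in self.volumes]
        if missing:
            raise ValueError(f"case {self.case_id!r}: missing modalities {missing}")
        extra = [m for m in self.volumes if m not in MODALITIES]
        if extra:
            raise ValueError(f"case {self.case_id!r}: unknown modalities {extra}")
        shapes = {m: np.asarray(v).shape for m, v in self.volumes.items()}
        for m, shp in shapes.items():
            if len(shp) != 3:
                raise ValueError(f"case {self.case_id!r}: modality {m} is not 3-D (shape {shp})")
        ref = shapes[MODALITIES[0]]
        for m, shp in shapes.items():
            if shp != ref:
                raise ValueError(
                    f"case {self.case_id!r}: shape mismatch — {MODALITIES[0]} is {ref} "
                    f"but {m} is {shp} (volumes must be co-registered)"
                )
        if not (0 <= int(self.mrs) <= N_CLASSES - 1):
            raise ValueError(f"case {self.case_id!r}: mrs {self.mrs} outside [0, {N_CLASSES - 1}]")
        self.mrs = int(self.mrs)

    @property
    def shape(self) -> tuple[int, int, int]:
        return np.asarray(self.volumes[MODALITIES[0]]).shape


@dataclass
class Dataset:
    """Ordered collection of cases with per-class counts."""

    cases: list = field(default_factory=list)

    @property
    def class_counts(self) -> dict:
        counts = {m: 0 for m in range(N_CLASSES)}
        for c in self.cases:
            counts[c.mrs] += 1
        return counts

    def __len__(self) -> int:
        return len(self.cases)

    def __iter__(self):
        return iter(self.cases)


def _load_volume(path: "str | Path") -> np.ndarray:
    img = nib.load(str(path))
    # keep the on-disk dtype; get_fdata would silently cast to float64
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected a 3-D volume, got shape {data.shape}")
    return data


def load_case(
    modality_paths: Mapping[str, "str | Path"],
    mrs: int,
    case_id: str = "case",
    clinical: Optional[ClinicalRecord] = None,
) -> StrokeCase:
    """Load one case from six NIfTI files, one per modality.

    Raises a descriptive error naming the absent modality or the mismatching
    shapes; voxel data are preserved losslessly (no dtype cast).
    """
    missing = [m for m in MODALITIES if m not in modality_paths]
    if missing:
        raise ValueError(f"case {case_id!r}: no path given for modalities {missing}")
    volumes = {m: _load_volume(modality_paths[m]) for m in MODALITIES}
    return StrokeCase(case_id=case_id, volumes=volumes, mrs=mrs, clinical=clinical)


_MANIFEST_COLS = ("case_id", "adc", "mtt", "ttp", "tmax", "cbv", "cbf", "mrs")


def load_dataset(manifest: "str | Path | pd.DataFrame") -> Dataset:
    """Load a dataset from a CSV manifest (case_id, adc..cbf paths, mrs).

    Case order follows manifest order; duplicate case ids are an error and
    any per-case failure is re-raised with the case id attached. Relative
    paths are resolved against the manifest's directory. Optional columns
    tss_minutes, ttt_minutes, tici_grade populate the clinical record.
    """
    if isinstance(manifest, pd.DataFrame):
        df, base = manifest, Path(".")
    else:
        df, base = pd.read_csv(manifest), Path(manifest).parent
    missing_cols = [c for c in _MANIFEST_COLS if c not in df.columns]
    if missing_cols:
        raise ValueError(f"manifest missing columns {missing_cols}")
    ids = df["case_id"].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate case ids in manifest: {dupes}")
    cases = []
    for _, row in df.iterrows():
        cid = str(row["case_id"])
        paths = {
            mod: (base / str(row[mod.lower()]) if not Path(str(row[mod.lower()])).is_absolute() else Path(str(row[mod.lower()])))
            for mod in MODALITIES
        }
        clinical = ClinicalRecord(
            tss_minutes=float(row["tss_minutes"]) if "tss_minutes" in df.columns and pd.notna(row.get("tss_minutes")) else None,
            ttt_minutes=float(row["ttt_minutes"]) if "ttt_minutes" in df.columns and pd.notna(row.get("ttt_minutes")) else None,
            tici_grade=str(row["tici_grade"]) if "tici_grade" in df.columns and pd.notna(row.get("tici_grade")) else None,
        )
        try:
            cases.append(load_case(paths, int(row["mrs"]), case_id=cid, clinical=clinical))
        except Exception as exc:
            raise type(exc)(f"while loading case {cid!r}: {exc}") from exc
    return Dataset(cases=cases)


def write_report(report: EvaluationReport, path: "str | Path") -> None:
    """Serialize a report as JSON plus a human-diffable confusion-matrix CSV."""
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    csv_path = path.with_suffix(".confusion.csv")
    with open(csv_path, "w", newline="") as fh:
        writer = csv.writer(fh)
        m = report.confusion.n_classes
        writer.writerow(["true\\pred"] + [str(j) for j in range(m)])
        for i, row in enumerate(report.confusion.table):
            writer.writerow([str(i)] + [int(v) for v in row])


def read_report(path: "str | Path") -> EvaluationReport:
    with open(path) as fh:
        return EvaluationReport.from_dict(json.load(fh))
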
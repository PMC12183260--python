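"""Regional gray-matter-volume extraction and between-sample calibration.

Regional GMV for a parcel is the sum of the voxel-wise GMV values inside
it.  An external validation cohort is calibrated to the training cohort by
shifting each regional column so that its mean matches the training mean
(additive offset only).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .synthgen import AtlasSpec, ParcellatedSubject

__all__ = [
    "RegionalGMVTable",
    "extract_regional_gmv",
    "read_labelled_image",
    "calibrate_to_training",
    "apply_offsets_to_subjects",
]


@dataclass
class RegionalGMVTable:
    """Subjects x parcels matrix of regional GMV sums plus covariates.

    ``data`` is indexed by subject id with one column per parcel name;
    ``meta`` shares the index and carries age, sex, site and label.
    """

    data: pd.DataFrame
    meta: pd.DataFrame

    def __post_init__(self):
        if not self.data.index.equals(self.meta.index):
            raise ValueError("data and meta must share the subject index")
        if self.data.isna().any().any():
            raise ValueError("regional GMV table contains missing entries")

    @property
    def d(self) -> int:
        return self.data.shape[1]

    @property
    def n(self) -> int:
        return self.data.shape[0]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    @property
    def labels(self) -> np.ndarray:
        return (self.meta["label"] == "PAT").to_numpy().astype(int)

    @property
    def covariates(self) -> np.ndarray:
        """Age and sex columns as an (n, 2) float array."""
        return self.meta[["age", "sex"]].to_numpy(dtype=float)

    def to_tsv(self, path) -> None:
        out = pd.concat([self.meta, self.data], axis=1)
        out.to_csv(Path(path), sep="\t", index=True, index_label="subject_id")

    @classmethod
    def from_tsv(cls, path) -> "RegionalGMVTable":
        df = pd.read_csv(Path(path), sep="\t", index_col="subject_id")
        meta_cols = ["age", "sex", "site", "label"]
        return cls(df.drop(columns=meta_cols), df[meta_cols])

    def copy(self) -> "RegionalGMVTable":
        return RegionalGMVTable(self.data.copy(), self.meta.copy())


def extract_regional_gmv(subjects: Sequence[ParcellatedSubject],
                         atlas: AtlasSpec) -> RegionalGMVTable:
    """Sum voxel-wise GMV within each parcel for every subject."""
    rows, meta = [], []
    for s in subjects:
        vals = []
        for pid in atlas.parcel_ids:
            if int(pid) not in s.voxels:
                raise ValueError(
                    f"subject {s.subject_id} is missing parcel {int(pid)}")
            vals.append(float(np.sum(s.voxels[int(pid)])))
        rows.append(vals)
        meta.append((s.subject_id, s.age, s.sex, s.site, s.label))
    idx = pd.Index([m[0] for m in meta], name="subject_id")
    data = pd.DataFrame(rows, index=idx, columns=list(atlas.parcel_names))
    meta_df = pd.DataFrame(
        [m[1:] for m in meta], index=idx,
        columns=["age", "sex", "site", "label"])
    return RegionalGMVTable(data, meta_df)


def read_labelled_image(gmv_image_path, label_image_path, atlas: AtlasSpec,
                        subject_id: str = "sub-img", **covariates
                        ) -> ParcellatedSubject:
    """Group voxel GMV values of a NIfTI image by an integer label image.

    Label 0 is background and is excluded; every atlas parcel must appear
    in the label image.
    """
    import nibabel as nib

    gmv = np.asanyarray(nib.load(str(gmv_image_path)).dataobj, dtype=float)
    labels = np.asanyarray(nib.load(str(label_image_path)).dataobj)
    labels = np.rint(labels).astype(int)
    if gmv.shape != labels.shape:
        raise ValueError(
            f"image shape {gmv.shape} != label shape {labels.shape}")
    present = set(np.unique(labels)) - {0}
    extra = present - set(int(p) for p in atlas.parcel_ids)
    if extra:
        raise ValueError(f"label image contains ids not in atlas: {sorted(extra)}")
    voxels = {}
    for pid in atlas.parcel_ids:
        mask = labels == int(pid)
        if not mask.any():
            raise ValueError(f"atlas parcel {int(pid)} absent from label image")
        voxels[int(pid)] = gmv[mask].ravel()
    return ParcellatedSubject(
        subject_id=subject_id, voxels=voxels,
        age=float(covariates.get("age", np.nan)),
        sex=int(covariates.get("sex", 0)),
        site=int(covariates.get("site", 0)),
        label=str(covariates.get("label", "HC")))


def calibrate_to_training(validation: RegionalGMVTable,
                          training: RegionalGMVTable):
    """Shift each validation column by (training mean - validation mean).

    Returns the calibrated table and the per-parcel offsets that were
    added, so the shift can be propagated to voxel-level data when SCNs are
    recomputed after calibration.  Idempotent: calibrating the result again
    yields zero offsets.
    """
    if validation.d != training.d:
        raise ValueError(
            f"parcel count mismatch: {validation.d} != {training.d}")
    offsets = (training.values.mean(axis=0)
               - validation.values.mean(axis=0))
    data = validation.data + offsets
    return RegionalGMVTable(data, validation.meta.copy()), offsets


def apply_offsets_to_subjects(subjects: Sequence[ParcellatedSubject],
                              offsets: np.ndarray,
                              atlas: AtlasSpec) -> list:
    """Propagate per-parcel regional offsets uniformly to voxel values.

    Each voxel of parcel r is shifted by offset_r / voxel_count_r, the
    minimal voxel-level change consistent with the regional calibration;
    per-subject SCNs can then be recomputed from the shifted voxels.
    """
    per_voxel = np.asarray(offsets, dtype=float) / atlas.voxel_counts
    out = []
    for s in subjects:
        vox = {int(pid): s.voxels[int(pid)] + per_voxel[i]
               for i, pid in enumerate(atlas.parcel_ids)}
        out.append(dataclasses.replace(s, voxels=vox))
    return out
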
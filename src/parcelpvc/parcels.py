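"""Parcel metadata, label-volume hygiene, and regional summarization.

This module consumes FreeSurfer-style labeled parcellations (it never
produces them): it relabels stray unsegmented voxels to their most common
labeled neighbor, builds the dilated brain mask used for whole-brain
goodness-of-fit, and reduces a PET image to per-parcel means, counts, and
volumes — the observation vector the geometric transfer matrix inverts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .volumes import LabelVolume, ScalarVolume

__all__ = [
    "TISSUE_CLASSES",
    "ParcelTable",
    "relabel_unsegmented",
    "brain_mask",
    "regional_means",
]

TISSUE_CLASSES = (
    "cortex",
    "wm",
    "deepgm",
    "csf",
    "ventricle",
    "brainstem",
    "cerebellum",
    "background",
)

_COLUMNS = ["label", "name", "tissue_class", "hemi", "paired_wm_label", "is_reference"]


@dataclass
class ParcelTable:
    """Per-parcel metadata: id, name, tissue class, hemisphere, WM pairing.

    Cortical rows carry the label of their paired subcortical white-matter
    parcel (used for the cortex-to-WM activity ratio); exactly one parcel is
    flagged as the SUVR reference region per analysis.
    """

    df: pd.DataFrame

    def __post_init__(self):
        df = self.df.copy()
        missing = [c for c in _COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"parcel table missing columns: {missing}")
        df["label"] = df["label"].astype(int)
        if df["label"].duplicated().any():
            dupes = df.loc[df["label"].duplicated(), "label"].tolist()
            raise ValueError(f"duplicate parcel labels: {dupes}")
        bad = set(df["tissue_class"]) - set(TISSUE_CLASSES)
        if bad:
            raise ValueError(f"unknown tissue classes: {sorted(bad)}")
        labels = set(df["label"])
        for _, row in df[df["tissue_class"] == "cortex"].iterrows():
            pw = row["paired_wm_label"]
            if pd.isna(pw) or int(pw) not in labels:
                raise ValueError(
                    f"cortex parcel {row['label']} has no valid paired WM label"
                )
        if int(df["is_reference"].sum()) != 1:
            raise ValueError("exactly one reference parcel must be flagged")
        self.df = df.reset_index(drop=True)

    # -- convenience accessors -------------------------------------------------
    @property
    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def labels_of_class(self, tissue_class: str) -> np.ndarray:
        return self.df.loc[
            self.df["tissue_class"] == tissue_class, "label"
        ].to_numpy()

    @property
    def reference_label(self) -> int:
        return int(self.df.loc[self.df["is_reference"], "label"].iloc[0])

    def cortex_wm_pairs(self) -> list[tuple[int, int]]:
        rows = self.df[self.df["tissue_class"] == "cortex"]
        return [(int(r["label"]), int(r["paired_wm_label"])) for _, r in rows.iterrows()]

    def name_of(self, label: int) -> str:
        return str(self.df.set_index("label").loc[int(label), "name"])

    # -- I/O -------------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ParcelTable":
        return cls(pd.read_csv(path, sep="\t"))


_NEIGHBOR_OFFSETS = [
    off for off in itertools.product((-1, 0, 1), repeat=3) if off != (0, 0, 0)
]


def relabel_unsegmented(
    labels: LabelVolume, unsegmented_ids: set[int] | list[int]
) -> LabelVolume:
    """Reassign voxels with unsegmented labels to their most common neighbor.

    Each offending voxel takes the most frequent label among its 26-connected
    labeled neighbors; voxels with no labeled neighbor wait for the next pass,
    so labels propagate inward in growing shells until none remain.  Ties are
    broken toward the lowest label id.  All other voxels are left untouched.
    """
    ids = {int(i) for i in np.atleast_1d(list(unsegmented_ids))}
    if not ids:
        raise ValueError("unsegmented_ids must be nonempty")
    arr = labels.data.copy()
    unseg = np.isin(arr, list(ids))
    if not unseg.any():
        return LabelVolume(arr, labels.affine.copy())
    if unseg.all():
        raise ValueError("volume contains only unsegmented labels; unresolvable")

    shape = arr.shape
    while unseg.any():
        coords = np.argwhere(unseg)
        new_vals = np.full(len(coords), -1, dtype=np.int64)
        for row, (i, j, k) in enumerate(coords):
            counts: dict[int, int] = {}
            for di, dj, dk in _NEIGHBOR_OFFSETS:
                ni, nj, nk = i + di, j + dj, k + dk
                if not (0 <= ni < shape[0] and 0 <= nj < shape[1] and 0 <= nk < shape[2]):
                    continue
                if unseg[ni, nj, nk]:
                    continue
                lab = int(arr[ni, nj, nk])
                counts[lab] = counts.get(lab, 0) + 1
            if counts:
                best = max(counts.items(), key=lambda kv: (kv[1], -kv[0]))[0]
                new_vals[row] = best
        assigned = new_vals >= 0
        if not assigned.any():
            raise ValueError(
                "unsegmented region is disconnected from any labeled voxel"
            )
        # synchronous update: one shell per pass
        ii, jj, kk = coords[assigned].T
        arr[ii, jj, kk] = new_vals[assigned]
        unseg[ii, jj, kk] = False
    return LabelVolume(arr, labels.affine.copy())


def brain_mask(labels: LabelVolume, dilation_voxels: int = 3) -> ScalarVolume:
    """Binary head mask: labeled region dilated by face-connected iterations.

    The 3-voxel dilation (the default) pads the parcellated brain so that
    spill of activity just outside the head is still inside the mask when
    the goodness-of-fit metric is evaluated over the whole brain.
    """
    if dilation_voxels < 0:
        raise ValueError("dilation_voxels must be >= 0")
    mask = labels.data > 0
    if dilation_voxels > 0:
        structure = ndimage.generate_binary_structure(3, 1)  # 6-connected
        mask = ndimage.binary_dilation(mask, structure, iterations=dilation_voxels)
    return ScalarVolume(mask.astype(np.float64), labels.affine.copy())


def regional_means(
    pet: ScalarVolume, labels: LabelVolume, parcels: ParcelTable
) -> pd.DataFrame:
    """Per-parcel mean activity, voxel count, and volume in mm^3.

    Empty parcels get a NaN mean and are flagged in the ``empty`` column
    rather than silently reported as 0.
    """
    if not pet.same_grid(labels):
        raise ValueError("PET and label volumes are not on the same grid")
    ids = parcels.labels
    arr = labels.data
    counts = np.array(
        ndimage.sum_labels(np.ones_like(arr, dtype=np.float64), arr, index=ids)
    )
    sums = np.array(ndimage.sum_labels(pet.data, arr, index=ids))
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    out = pd.DataFrame(
        {
            "label": ids,
            "name": [parcels.name_of(i) for i in ids],
            "mean": means,
            "n_voxels": counts.astype(int),
            "volume_mm3": counts * labels.voxel_volume_mm3,
            "empty": counts == 0,
        }
    )
    return out
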
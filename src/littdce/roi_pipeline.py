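"""ROI curve extraction, ROI propagation across visits, FLAIR area.

Images and masks are NIfTI volumes sharing one grid; dynamic images are
4D (x, y, z, t).  ROI drawing itself is a manual step upstream — this
module consumes binary masks (the synthetic cohort generator emits
ground-truth rim masks).  Physical areas come from the NIfTI voxel
dimensions.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import SignalCurve
from .signal_model import AcquisitionProtocol

__all__ = [
    "ROIMask",
    "VisitRecord",
    "mean_roi_curve",
    "transfer_roi",
    "flair_max_slice_area",
    "load_manifest",
]


@dataclass(frozen=True)
class ROIMask:
    """Binary 3D mask with its voxel dimensions in mm."""

    data: np.ndarray
    voxel_size_mm: Tuple[float, float, float]

    def __post_init__(self) -> None:
        d = np.asarray(self.data).astype(bool)
        if d.ndim != 3:
            raise ValueError("mask must be 3-dimensional")
        object.__setattr__(self, "data", d)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @classmethod
    def from_nifti(cls, path: str | Path) -> "ROIMask":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        return cls(np.asanyarray(img.dataobj) > 0.5, tuple(float(z) for z in zooms))


@dataclass(frozen=True)
class VisitRecord:
    """One row of the visit manifest: which image/ROI belongs to which
    subject-day, with day 0 = the ablation procedure."""

    subject: str
    day: int
    image_path: str
    mask_path: str
    aif_voxel: Tuple[int, int, int]
    protocol: AcquisitionProtocol


def mean_roi_curve(
    image: np.ndarray, mask: ROIMask, protocol: AcquisitionProtocol
) -> SignalCurve:
    """Frame-wise arithmetic mean signal over the masked voxels."""
    img = np.asarray(image, dtype=float)
    if img.ndim != 4:
        raise ValueError("dynamic image must be 4-dimensional (x, y, z, t)")
    if img.shape[:3] != mask.data.shape:
        raise ValueError(
            f"image grid {img.shape[:3]} does not match mask grid {mask.data.shape}"
        )
    if mask.n_voxels == 0:
        raise ValueError("ROI mask is empty")
    vals = img[mask.data, :].mean(axis=0)
    times = protocol.frame_times()[: img.shape[3]]
    return SignalCurve(times, np.maximum(vals, 0.0))


def transfer_roi(
    mask: ROIMask,
    target_shape: Tuple[int, int, int],
    target_voxel_size_mm: Tuple[float, float, float],
) -> ROIMask:
    """Propagate an ROI to another visit acquired on the same grid.

    Only the co-registered case is supported: identical shape and voxel
    size yield a voxel-identical copy; any mismatch raises — no
    resampling or registration is attempted.
    """
    if tuple(target_shape) != mask.data.shape:
        raise ValueError(
            "ROI transfer requires identical grids; "
            f"got {mask.data.shape} -> {tuple(target_shape)} (registration "
            "is not implemented)"
        )
    if not np.allclose(target_voxel_size_mm, mask.voxel_size_mm):
        raise ValueError(
            "ROI transfer requires identical voxel sizes; "
            f"got {mask.voxel_size_mm} -> {tuple(target_voxel_size_mm)}"
        )
    return ROIMask(mask.data.copy(), mask.voxel_size_mm)


def flair_max_slice_area(flair_mask: np.ndarray, pixel_area_mm2: float) -> float:
    """Area of the single axial slice where the abnormality is maximal.

    ``flair_mask`` is a 3D binary mask with slices along the last axis;
    an empty mask yields 0.
    """
    m = np.asarray(flair_mask).astype(bool)
    if m.ndim != 3:
        raise ValueError("FLAIR mask must be 3-dimensional")
    if pixel_area_mm2 <= 0:
        raise ValueError("pixel area must be positive")
    counts = m.sum(axis=(0, 1))
    return float(counts.max() * pixel_area_mm2)


def load_manifest(
    path: str | Path, protocol: Optional[AcquisitionProtocol] = None
) -> list[VisitRecord]:
    """Read a visit manifest CSV (subject, day, image, mask, aif i/j/k)."""
    df = pd.read_csv(path)
    required = {"subject", "day", "image_path", "mask_path",
                "aif_i", "aif_j", "aif_k"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest is missing columns: {sorted(missing)}")
    proto = protocol or AcquisitionProtocol()
    records = []
    for _, row in df.iterrows():
        records.append(
            VisitRecord(
                subject=str(row["subject"]),
                day=int(row["day"]),
                image_path=str(row["image_path"]),
                mask_path=str(row["mask_path"]),
                aif_voxel=(int(row["aif_i"]), int(row["aif_j"]), int(row["aif_k"])),
                protocol=proto,
            )
        )
    return records
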
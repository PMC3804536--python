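"""Dynamic-image handling: frame summation and ROI time-activity extraction.

Voxel values of reconstructed dynamic PET are frame-averaged activity
concentrations (kBq/mL), so extracting a TAC is a plain per-frame mean over
the mask — no division by frame duration.  Images travel as 4D NIfTI with a
sidecar CSV of frame timings; masks as 3D integer NIfTI.
"""

from __future__ import annotations

from dataclasses import dataclass

import nibabel as nib
import numpy as np
import pandas as pd

from .curves import FrameSchedule, TimeActivityCurve

ROI_LABELS = ("lv_blood_pool", "anterolateral_myocardium")


@dataclass
class DynamicImage:
    """Voxel grid x frames, with the acquisition frame schedule."""

    data: np.ndarray  # shape (nx, ny, nz, n_frames)
    frames: FrameSchedule
    voxel_size_mm: tuple[float, float, float] = (0.8, 0.8, 0.8)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D array, got shape {self.data.shape}")
        if self.data.shape[3] != self.frames.n_frames:
            raise ValueError(
                f"{self.data.shape[3]} image frames vs "
                f"{self.frames.n_frames} schedule frames"
            )


@dataclass
class RoiMask:
    """Boolean voxel mask with a named anatomical label."""

    mask: np.ndarray
    label: str

    def __post_init__(self):
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.ndim != 3:
            raise ValueError("mask must be 3D")
        if not self.mask.any():
            raise ValueError(f"ROI mask '{self.label}' is empty")


def sum_frames(img: DynamicImage) -> np.ndarray:
    """Duration-weighted sum over frames, yielding one static 3D image.

    Multiplying each frame's mean concentration by its duration and summing
    gives the total time-integrated activity per voxel — the image analysts
    draw ROIs on.
    """
    return np.tensordot(img.data, img.frames.durations, axes=([3], [0]))


def extract_tac(img: DynamicImage, roi: RoiMask) -> TimeActivityCurve:
    """Per-frame mean over the mask voxels, timing copied from the image."""
    if roi.mask.shape != img.data.shape[:3]:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match image grid {img.data.shape[:3]}"
        )
    values = img.data[roi.mask].mean(axis=0)
    units = "kBq/mL" if roi.label == "lv_blood_pool" else "kBq/g"
    return TimeActivityCurve(img.frames, values, units=units)


# ---------------------------------------------------------------------------
# NIfTI round-trips


def _affine(voxel_size_mm) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size_mm
    return aff


def save_dynamic(img: DynamicImage, nifti_path, timing_csv_path) -> None:
    nib.save(nib.Nifti1Image(img.data, _affine(img.voxel_size_mm)), str(nifti_path))
    pd.DataFrame(
        {
            "frame_start_min": img.frames.starts,
            "frame_duration_min": img.frames.durations,
        }
    ).to_csv(timing_csv_path, index=False)


def load_dynamic(nifti_path, timing_csv_path) -> DynamicImage:
    nii = nib.load(str(nifti_path))
    timing = pd.read_csv(timing_csv_path)
    frames = FrameSchedule(
        timing["frame_start_min"].to_numpy(), timing["frame_duration_min"].to_numpy()
    )
    vox = tuple(float(v) for v in nii.header.get_zooms()[:3])
    return DynamicImage(np.asarray(nii.dataobj, dtype=float), frames, vox)


def save_mask(roi: RoiMask, nifti_path, voxel_size_mm=(0.8, 0.8, 0.8)) -> None:
    nib.save(
        nib.Nifti1Image(roi.mask.astype(np.uint8), _affine(voxel_size_mm)),
        str(nifti_path),
    )


def load_mask(nifti_path, label: str) -> RoiMask:
    nii = nib.load(str(nifti_path))
    return RoiMask(np.asarray(nii.dataobj) > 0, label)
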
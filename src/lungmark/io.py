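"""Reading and writing the imaging and tabular formats the pipeline touches.

Conventions used throughout the package:

* volumes are indexed ``(slice, row, col)``, 0-based ("slice-major");
* CT intensities are in Hounsfield units (HU) after DICOM rescale;
* masks are strict ``{0, 1}`` arrays on the same voxel grid as their CT
  volume — no resampling is performed, features are computed in native
  pixel units.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd


class AlignmentError(ValueError):
    """Image/mask geometry disagreement."""


class MetadataError(ValueError):
    """Required imaging metadata absent."""


@dataclass
class CTVolume:
    """A stack of 2-D CT slices in Hounsfield units.

    Attributes
    ----------
    voxels : (n_slices, n_rows, n_cols) float array, HU
    pixel_spacing : (row_mm, col_mm) in-plane spacing
    slice_thickness : slice spacing in mm
    """

    voxels: np.ndarray
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 3:
            raise ValueError("CT voxels must be 3-D (slice, row, col)")
        if min(self.pixel_spacing) <= 0 or self.slice_thickness <= 0:
            raise MetadataError("pixel spacing and slice thickness must be positive")

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.pixel_spacing[0] * self.pixel_spacing[1] * self.slice_thickness)


@dataclass
class MaskVolume:
    """A binary per-slice mask (tumor or lung field) on a CT voxel grid."""

    voxels: np.ndarray
    kind: Literal["tumor", "lung"] = "tumor"
    pixel_spacing: tuple[float, float] = (1.0, 1.0)
    slice_thickness: float = 1.0

    def __post_init__(self):
        v = np.asarray(self.voxels)
        if v.ndim != 3:
            raise ValueError("mask voxels must be 3-D (slice, row, col)")
        self.voxels = (v > 0).astype(np.uint8)

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    def validate_against(self, ct: "CTVolume | MaskVolume") -> None:
        if self.voxels.shape != ct.voxels.shape:
            raise AlignmentError(
                f"mask shape {self.voxels.shape} does not match volume shape {ct.voxels.shape}"
            )


# ---------------------------------------------------------------------------
# NIfTI
# ---------------------------------------------------------------------------

def _nifti_to_stack(path):
    import nibabel as nib

    img = nib.load(os.fspath(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 2:
        data = data[..., np.newaxis]
    if data.ndim != 3:
        raise ValueError(f"expected a 3-D NIfTI, got shape {data.shape}")
    zooms = img.header.get_zooms()[:3]
    # stored (x, y, z) -> package convention (slice, row, col)
    stack = np.transpose(data, (2, 1, 0))
    spacing = (float(zooms[1]), float(zooms[0]))
    thickness = float(zooms[2])
    return stack, spacing, thickness


def _stack_to_nifti(stack, spacing, thickness, path):
    import nibabel as nib

    data = np.transpose(np.asarray(stack), (2, 1, 0))
    affine = np.diag([spacing[1], spacing[0], thickness, 1.0])
    nib.save(nib.Nifti1Image(data, affine), os.fspath(path))


def save_ct_volume(ct: CTVolume, path) -> None:
    """Write a CTVolume as NIfTI-1 (float32 HU)."""
    _stack_to_nifti(ct.voxels.astype(np.float32), ct.pixel_spacing, ct.slice_thickness, path)


def save_mask_volume(mask: MaskVolume, path) -> None:
    """Write a MaskVolume as NIfTI-1 (uint8 {0,1})."""
    _stack_to_nifti(mask.voxels.astype(np.uint8), mask.pixel_spacing, mask.slice_thickness, path)


# ---------------------------------------------------------------------------
# DICOM series
# ---------------------------------------------------------------------------

def _load_dicom_series(path) -> CTVolume:
    import pydicom

    files = sorted(p for p in Path(path).iterdir() if p.is_file())
    datasets = []
    for p in files:
        try:
            datasets.append(pydicom.dcmread(os.fspath(p)))
        except Exception:  # non-DICOM file in the directory
            continue
    if not datasets:
        raise FileNotFoundError(f"no DICOM files under {path}")
    uids = {getattr(ds, "SeriesInstanceUID", None) for ds in datasets}
    if len(uids) > 1:
        raise AlignmentError(f"directory mixes {len(uids)} DICOM series")

    # order along the acquisition axis: ImagePositionPatient projected on the
    # slice normal; fall back to InstanceNumber
    ref = datasets[0]
    try:
        iop = np.asarray(ref.ImageOrientationPatient, float)
        normal = np.cross(iop[:3], iop[3:])
        datasets.sort(key=lambda ds: float(np.dot(np.asarray(ds.ImagePositionPatient, float), normal)))
    except Exception:
        datasets.sort(key=lambda ds: int(getattr(ds, "InstanceNumber", 0)))

    slices = []
    for ds in datasets:
        if "RescaleSlope" not in ds or "RescaleIntercept" not in ds:
            raise MetadataError("DICOM slice missing rescale slope/intercept")
        slices.append(ds.pixel_array.astype(float) * float(ds.RescaleSlope) + float(ds.RescaleIntercept))
    try:
        ps = ref.PixelSpacing
        spacing = (float(ps[0]), float(ps[1]))
        thickness = float(getattr(ref, "SpacingBetweenSlices", None) or ref.SliceThickness)
    except Exception as exc:
        raise MetadataError("DICOM series missing pixel spacing / slice thickness") from exc
    return CTVolume(np.stack(slices), spacing, thickness)


def load_ct_volume(path, format: Literal["dicom_series", "nifti", None] = None) -> CTVolume:
    """Load a CT volume from a NIfTI file or a single-series DICOM directory.

    Voxels are returned in HU (DICOM rescale slope/intercept applied), slices
    sorted along the acquisition axis. ``format=None`` infers from the path.
    """
    path = Path(path)
    if format is None:
        format = "dicom_series" if path.is_dir() else "nifti"
    if format == "dicom_series":
        return _load_dicom_series(path)
    stack, spacing, thickness = _nifti_to_stack(path)
    return CTVolume(stack.astype(float), spacing, thickness)


def load_mask_volume(
    path,
    format: Literal["nifti", "png_stack", None] = None,
    kind: Literal["tumor", "lung"] = "tumor",
    reference: CTVolume | None = None,
) -> MaskVolume:
    """Load a binary mask from NIfTI or a directory of per-slice PNGs.

    Any positive stored value becomes foreground. When ``reference`` is given
    the mask geometry is validated against it (shape mismatch raises
    :class:`AlignmentError`) and its spacing is copied.
    """
    path = Path(path)
    if format is None:
        format = "png_stack" if path.is_dir() else "nifti"
    if format == "png_stack":
        import imageio.v3 as iio

        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".png")
        if not files:
            raise FileNotFoundError(f"no PNG slices under {path}")
        stack = np.stack([np.asarray(iio.imread(os.fspath(p))) for p in files])
        if stack.ndim == 4:  # RGB(A) -> any positive channel
            stack = stack.max(axis=-1)
        spacing, thickness = (1.0, 1.0), 1.0
    else:
        stack, spacing, thickness = _nifti_to_stack(path)
    if reference is not None:
        spacing, thickness = reference.pixel_spacing, reference.slice_thickness
    mask = MaskVolume(stack, kind=kind, pixel_spacing=spacing, slice_thickness=thickness)
    if reference is not None:
        mask.validate_against(reference)
    return mask


# ---------------------------------------------------------------------------
# Tables
# ---------------------------------------------------------------------------

REQUIRED_CLINICAL_COLUMNS = ("patient_id", "survival_time", "event")
FEATURE_COLUMNS = ("convexity", "entropy_core", "entropy_boundary", "entropy_ratio", "volume")


def read_clinical_table(path) -> pd.DataFrame:
    """Read and validate a clinical CSV (patient_id, survival_time in days,
    event in {0,1}, optional covariates)."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing required columns: {missing}")
    df = df.copy()
    df["patient_id"] = df["patient_id"].astype(str)
    df["survival_time"] = df["survival_time"].astype(float)
    df["event"] = df["event"].astype(int)
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dup}")
    if (df["survival_time"] < 0).any():
        raise ValueError("survival_time must be >= 0")
    if not df["event"].isin([0, 1]).all():
        raise ValueError("event must be 0 (censored) or 1 (death)")
    return df


def write_feature_table(rows: Iterable[dict] | pd.DataFrame, path) -> None:
    """Write one row per tumor with the extracted feature columns as CSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    df.to_csv(path, index=False)


def read_feature_table(path) -> pd.DataFrame:
    return pd.read_csv(path)
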
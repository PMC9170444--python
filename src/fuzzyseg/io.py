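"""NIfTI and table I/O plus brain-mask extraction.

Volumes travel as NIfTI-1 (.nii / .nii.gz) via nibabel; voxel sizes come
from the header zooms, and 2-D images are written/read as single-slice
volumes. Parameter tables are delimited text with a (subject, group,
parameter, value) header.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from skimage import filters, measure, morphology

from .exceptions import DataFormatError, NumericalError
from .image import OUTSIDE_LABEL, GrayImage, as_gray_image

__all__ = [
    "read_volume",
    "write_volume",
    "write_membership",
    "extract_brain_mask",
    "read_parameter_table",
]


def read_volume(path, mask_path=None) -> GrayImage:
    """Load a NIfTI volume (2-D accepted as a single-slice volume)."""
    try:
        img = nib.load(str(path))
        data = np.asarray(img.get_fdata(), dtype=float)
    except Exception as exc:  # nibabel raises a zoo of format errors
        raise DataFormatError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.squeeze(data)
    if data.ndim not in (2, 3):
        raise DataFormatError(
            f"{path}: expected a 2-D or 3-D volume, got {data.ndim} axes")
    zooms = img.header.get_zooms()[:data.ndim]
    mask = None
    if mask_path is not None:
        m = read_volume(mask_path)
        if m.shape != data.shape:
            raise DataFormatError("mask and image shapes differ")
        mask = m.intensities > 0
    return GrayImage(data, tuple(float(z) for z in zooms), mask)


def _affine(voxel_size, ndim3: int = 3) -> np.ndarray:
    vs = list(voxel_size) + [1.0] * (ndim3 - len(voxel_size))
    return np.diag(vs[:3] + [1.0])


def write_volume(data, path, voxel_size=None) -> None:
    """Write an array or GrayImage as NIfTI-1; integer data stay integral."""
    if isinstance(data, GrayImage):
        voxel_size = data.voxel_size if voxel_size is None else voxel_size
        data = data.intensities
    arr = np.asarray(data)
    if voxel_size is None:
        voxel_size = (1.0,) * arr.ndim
    if np.issubdtype(arr.dtype, np.integer):
        arr = arr.astype(np.int16)
    else:
        arr = arr.astype(np.float64)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), str(path))


def write_membership(membership_volumes: np.ndarray, path,
                     voxel_size=None) -> None:
    """Write a (..., f) membership stack as a 4-D NIfTI in [0, 1]."""
    arr = np.asarray(membership_volumes, dtype=np.float64)
    vs = (1.0,) * (arr.ndim - 1) if voxel_size is None else tuple(voxel_size)
    nib.save(nib.Nifti1Image(arr, _affine(vs)), str(path))


def extract_brain_mask(image, threshold="otsu", closing_radius: int = 2
                       ) -> np.ndarray:
    """Threshold + largest connected component + binary closing.

    ``threshold`` is ``"otsu"`` or a fraction of the maximum intensity.
    Deterministic; raises on constant images or empty foreground.
    """
    img = as_gray_image(image)
    data = img.intensities
    if np.ptp(data) == 0.0:
        raise NumericalError("constant image: cannot extract a brain mask")
    if threshold == "otsu":
        thr = filters.threshold_otsu(data)
    else:
        thr = float(threshold) * float(data.max())
    fg = data > thr
    if not fg.any():
        raise NumericalError("empty foreground after thresholding")
    comp = measure.label(fg)
    largest = np.argmax(np.bincount(comp.ravel())[1:]) + 1
    mask = comp == largest
    if closing_radius > 0:
        footprint = (morphology.ball(closing_radius) if data.ndim == 3
                     else morphology.disk(closing_radius))
        mask = morphology.binary_closing(mask, footprint)
    return mask


def read_parameter_table(path) -> pd.DataFrame:
    """Read a (subject, group, parameter, value) delimited-text table."""
    try:
        df = pd.read_csv(path, sep=None, engine="python")
    except Exception as exc:
        raise DataFormatError(f"cannot read parameter table {path}: {exc}") \
            from exc
    df.columns = [str(c).strip().lower() for c in df.columns]
    needed = {"subject", "group", "parameter", "value"}
    if not needed <= set(df.columns):
        raise DataFormatError(
            f"parameter table must have columns {sorted(needed)}")
    df["group"] = df["group"].str.strip().str.lower()
    return df
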
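"""Container for grayscale MR images.

A :class:`GrayImage` couples a 2-D slice or 3-D volume of scalar intensities
with its physical voxel size and an optional binary brain mask. Clustering
operates on the flattened in-mask voxels only: non-brain voxels (scalp,
skull, background) are excluded from the pixel set entirely, mirroring the
skull-stripping step that precedes tissue segmentation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DimensionError

#: Label written outside the brain mask in crisp label maps.
OUTSIDE_LABEL = -1


@dataclass
class GrayImage:
    """A 2-D/3-D scalar intensity image with voxel geometry and optional mask.

    Parameters
    ----------
    intensities
        Array of finite scalar intensities with 2 or 3 axes.
    voxel_size
        Physical extent of one voxel along each axis, in millimetres.
    mask
        Optional boolean array of the same shape; ``True`` marks in-brain
        voxels. ``None`` means every voxel is inside.
    """

    intensities: np.ndarray
    voxel_size: tuple[float, ...] = None  # type: ignore[assignment]
    mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim not in (2, 3):
            raise DimensionError(
                f"expected a 2-D or 3-D image, got {self.intensities.ndim} axes"
            )
        if not np.all(np.isfinite(self.intensities)):
            raise DimensionError("image intensities must be finite")
        if self.voxel_size is None:
            self.voxel_size = (1.0,) * self.intensities.ndim
        self.voxel_size = tuple(float(v) for v in self.voxel_size)
        if len(self.voxel_size) != self.intensities.ndim:
            raise DimensionError("voxel_size must have one entry per image axis")
        if self.mask is not None:
            self.mask = np.asarray(self.mask, dtype=bool)
            if self.mask.shape != self.intensities.shape:
                raise DimensionError("mask shape must match image shape")
            if not self.mask.any():
                raise DimensionError("mask selects no voxels")

    # -- convenience views -------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.intensities.shape

    @property
    def ndim(self) -> int:
        return self.intensities.ndim

    @property
    def n_voxels(self) -> int:
        """Number of in-mask voxels (the clustering sample size n)."""
        if self.mask is None:
            return self.intensities.size
        return int(self.mask.sum())

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    def masked_values(self) -> np.ndarray:
        """The flattened in-mask intensities, shape ``(n,)``."""
        if self.mask is None:
            return self.intensities.ravel()
        return self.intensities[self.mask]

    def embed(self, flat: np.ndarray, fill: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back into the full image geometry."""
        flat = np.asarray(flat)
        if self.mask is None:
            return flat.reshape(self.shape)
        out = np.full(self.shape, fill, dtype=flat.dtype)
        out[self.mask] = flat
        return out

    def with_intensities(self, intensities: np.ndarray) -> "GrayImage":
        """A copy sharing geometry and mask but holding new intensities."""
        return GrayImage(intensities, self.voxel_size, self.mask)


def as_gray_image(image, voxel_size=None, mask=None) -> GrayImage:
    """Coerce an array or GrayImage to a GrayImage."""
    if isinstance(image, GrayImage):
        return image
    return GrayImage(np.asarray(image, dtype=float), voxel_size, mask)
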
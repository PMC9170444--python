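"""Intuitionistic fuzzification of grayscale images.

An intuitionistic fuzzy set attaches to each pixel a membership degree b, a
non-membership degree a and a hesitation degree pi with b + a + pi = 1. The
gray level is first min-max normalised to b0 in [0, 1]; the quadratic
(Yager-type) generator then gives

    b  = b0**2,   a = (1 - b0)**2,   pi = 2 * b0 * (1 - b0),

an exact partition of unity. Hesitation is largest (0.5) at mid-gray, where
a pixel is most ambiguous between dark and bright, and vanishes at the
extremes. The hesitation image later down-weights the losing memberships in
the improved clustering loop.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import DegenerateRangeError, DomainError
from .image import GrayImage, as_gray_image

__all__ = [
    "IFSImage",
    "normalize_gray",
    "intuitionistic_fuzzify",
    "ifs_defuzzify",
]


@dataclass
class IFSImage:
    """Per-pixel (membership, non-membership, hesitation) triplets.

    All three arrays share the source image's shape and sum to one
    elementwise. ``gray_range`` records the (masked) min/max of the source
    so the fuzzification can be inverted.
    """

    membership: np.ndarray
    nonmembership: np.ndarray
    hesitation: np.ndarray
    gray_range: tuple[float, float] = (0.0, 1.0)


def normalize_gray(image) -> np.ndarray:
    """Min-max normalise intensities to [0, 1] over the mask.

    Outside the mask the output is zero. The extrema are taken over masked
    voxels only; a constant (zero-range) image is rejected.
    """
    img = as_gray_image(image)
    vals = img.masked_values()
    lo, hi = float(vals.min()), float(vals.max())
    if hi <= lo:
        raise DegenerateRangeError("image is constant over the mask")
    b0 = img.embed((vals - lo) / (hi - lo))
    return b0


def intuitionistic_fuzzify(b0: np.ndarray,
                           gray_range: tuple[float, float] = (0.0, 1.0)
                           ) -> IFSImage:
    """Apply the quadratic generator to a normalised gray image."""
    b0 = np.asarray(b0, dtype=float)
    if b0.min() < 0.0 or b0.max() > 1.0:
        raise DomainError("normalised gray levels must lie in [0, 1]")
    b = b0**2
    a = (1.0 - b0) ** 2
    pi = 2.0 * b0 * (1.0 - b0)
    return IFSImage(b, a, pi, (float(gray_range[0]), float(gray_range[1])))


def fuzzify_image(image) -> IFSImage:
    """Normalise then fuzzify a grayscale image in one step."""
    img = as_gray_image(image)
    vals = img.masked_values()
    out = intuitionistic_fuzzify(normalize_gray(img),
                                 (float(vals.min()), float(vals.max())))
    return out


def ifs_defuzzify(ifs: IFSImage, gray_range: tuple[float, float] | None = None
                  ) -> GrayImage:
    """Invert fuzzification: m = m_min + sqrt(b) * (m_max - m_min)."""
    lo, hi = ifs.gray_range if gray_range is None else gray_range
    b = np.clip(ifs.membership, 0.0, 1.0)
    return GrayImage(lo + np.sqrt(b) * (hi - lo))


def membership_to_gray(b: np.ndarray, gray_range: tuple[float, float]
                       ) -> np.ndarray:
    """Map membership-domain values back to the original gray scale."""
    lo, hi = gray_range
    return lo + np.sqrt(np.clip(np.asarray(b, dtype=float), 0.0, 1.0)) * (hi - lo)
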
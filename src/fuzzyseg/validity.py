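"""Cluster validity indices for fuzzy partitions.

Three canonical indices compare the quality of fuzzy segmentations:

* partition coefficient ``Vpc = (1/n) sum b_xy^2`` — crispness; 1 for a
  crisp partition, 1/f for a maximally ambiguous one (higher is better);
* partition entropy ``Vpe = -(1/n) sum b_xy ln b_xy`` — ambiguity; 0 for a
  crisp partition, ln f at the uniform one (lower is better);
* Xie-Beni index ``Vxb = sum b_xy^l r_xy^2 / (n * min_{x!=e} |a_x - a_e|^2)``
  — within-cluster compactness over between-center separation (lower is
  better); invariant under rescaling of the intensity axis.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from .exceptions import DegenerateCentersError, DimensionError
from .image import as_gray_image

__all__ = [
    "partition_coefficient",
    "partition_entropy",
    "xie_beni",
    "ValidityReport",
    "validity_report",
]


def _B(membership) -> np.ndarray:
    B = np.asarray(membership, dtype=float)
    if B.ndim != 2 or B.size == 0:
        raise DimensionError("membership matrix must be a non-empty f x n array")
    return B


def partition_coefficient(membership) -> float:
    B = _B(membership)
    return float(np.sum(B**2) / B.shape[1])


def partition_entropy(membership) -> float:
    B = _B(membership)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(B > 0, B * np.log(np.where(B > 0, B, 1.0)), 0.0)
    return float(-terms.sum() / B.shape[1])


def xie_beni(image, membership, centers, fuzzifier: float = 2.0) -> float:
    m = as_gray_image(image).masked_values()
    B = _B(membership)
    a = np.asarray(centers, dtype=float)
    sep = np.min((a[:, None] - a[None, :]) ** 2
                 + np.diag(np.full(a.size, np.inf)))
    if sep == 0.0:
        raise DegenerateCentersError("coincident centers: Xie-Beni undefined")
    r2 = (m[None, :] - a[:, None]) ** 2
    return float(np.sum(B**fuzzifier * r2) / (m.size * sep))


@dataclass
class ValidityReport:
    """Bundle of the three indices plus problem size."""

    vpc: float
    vpe: float
    vxb: float
    n: int
    f: int

    def to_dict(self) -> dict:
        return asdict(self)


def validity_report(image, membership, centers, fuzzifier: float = 2.0
                    ) -> ValidityReport:
    B = _B(membership)
    return ValidityReport(
        vpc=partition_coefficient(B),
        vpe=partition_entropy(B),
        vxb=xie_beni(image, B, centers, fuzzifier),
        n=B.shape[1],
        f=B.shape[0],
    )
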
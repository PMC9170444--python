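"""Synthetic brain phantoms with spin-echo contrast and ground truth.

No patient data accompany this package, so segmentation quality is measured
on simulated volumes. A phantom is a nested set of concentric ellipsoidal
tissue shells (CSF rim, gray-matter ribbon, white-matter core, optional
off-center tumor blob) whose class intensities follow the spin-echo signal
equation

    S = beta * (1 - exp(-TR / T1)) * exp(-TE / T2)

evaluated at the acquisition's repetition time TR and echo time TE, with
literature-typical 3 T relaxation times per tissue. Seeded Gaussian, Rician
or salt-and-pepper noise can be added inside the brain mask. The generator
returns the image, the ground-truth label map and the tissue table, and is
bit-reproducible given a seed.

Geometry is assigned by ranking voxels on their ellipsoidal radius and
cutting the ranking at exact per-tissue voxel counts, so requested counts
are honoured voxel-for-voxel (useful for volumetry oracles). What the
phantom deliberately does not emulate: anatomy-shaped cortical folding,
partial-volume mixing, bias fields and multi-coil noise correlation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import DataFormatError, DomainError
from .image import OUTSIDE_LABEL, GrayImage

__all__ = [
    "TissueSpec",
    "AcquisitionSpec",
    "PhantomTruth",
    "spin_echo_signal",
    "make_phantom",
    "corrupt",
    "default_tissues",
    "min_class_contrast",
]


@dataclass(frozen=True)
class TissueSpec:
    """One tissue class: name, T1/T2 relaxation times (ms), spin density."""

    name: str
    t1: float
    t2: float
    density: float = 1.0

    def __post_init__(self):
        if self.t1 <= 0 or self.t2 <= 0 or self.density < 0:
            raise DomainError("need t1 > 0, t2 > 0, density >= 0")


@dataclass(frozen=True)
class AcquisitionSpec:
    """Spin-echo acquisition: repetition time TR and echo time TE (ms)."""

    tr: float = 1980.0
    te: float = 2.28
    voxel_size: tuple[float, ...] = (1.0, 1.0, 1.0)

    def __post_init__(self):
        if self.tr <= 0 or self.te < 0:
            raise DomainError("need tr > 0 and te >= 0")


def default_tissues(with_tumor: bool = True) -> list[TissueSpec]:
    """Literature-typical 3 T tissue parameters (ms), unit spin density."""
    tissues = [
        TissueSpec("CSF", t1=4000.0, t2=2000.0),
        TissueSpec("GM", t1=1300.0, t2=110.0),
        TissueSpec("WM", t1=830.0, t2=80.0),
    ]
    if with_tumor:
        tissues.append(TissueSpec("tumor", t1=1600.0, t2=150.0))
    return tissues


def spin_echo_signal(tissue: TissueSpec, acq: AcquisitionSpec) -> float:
    """Spin-echo signal beta * (1 - e^{-TR/T1}) * e^{-TE/T2} for one tissue."""
    return float(tissue.density
                 * (1.0 - np.exp(-acq.tr / tissue.t1))
                 * np.exp(-acq.te / tissue.t2))


def min_class_contrast(tissues, acq=AcquisitionSpec()) -> float:
    """Smallest intensity gap between adjacent (sorted) tissue signals."""
    s = np.sort([spin_echo_signal(t, acq) for t in tissues])
    return float(np.min(np.diff(s)))


@dataclass
class PhantomTruth:
    """Generated image + ground-truth labels + provenance."""

    image: GrayImage
    labels: np.ndarray
    tissues: list[TissueSpec]
    acquisition: AcquisitionSpec
    noise: dict = field(default_factory=dict)

    def to_sidecar(self) -> dict:
        """JSON-serialisable description sufficient to regenerate."""
        return {
            "tissues": [vars(t) for t in self.tissues],
            "acquisition": {"tr": self.acquisition.tr,
                            "te": self.acquisition.te,
                            "voxel_size": list(self.acquisition.voxel_size)},
            "noise": self.noise,
        }


def _ellipsoid_radius(shape) -> np.ndarray:
    center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
    semi = 0.45 * np.asarray(shape, dtype=float)
    grids = np.meshgrid(*[np.arange(s, dtype=float) for s in shape],
                        indexing="ij")
    rho2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return np.sqrt(rho2)


def make_phantom(shape=(64, 64, 64), tissues=None, acquisition=None,
                 counts=None, tumor_fraction: float = 0.04,
                 noise_model: str = "gaussian", noise_level: float = 0.0,
                 seed: int = 0) -> PhantomTruth:
    """Build a concentric-shell brain phantom with exact tissue counts.

    Parameters
    ----------
    shape
        Image shape, 2-D or 3-D.
    tissues
        Tissue table, listed outermost-to-innermost; a tissue named
        ``"tumor"`` (any case) becomes an off-center blob carved out of the
        innermost shell. Defaults to CSF/GM/WM/tumor.
    counts
        Optional dict tissue-name -> exact voxel count. By default the
        brain occupies the ellipsoid of relative radius 1 and is split
        20% CSF / 30% GM / remainder WM, with ``tumor_fraction`` of the
        brain turned into tumor.
    noise_model, noise_level, seed
        Passed to :func:`corrupt`; level 0 leaves the image noiseless.
    """
    tissues = list(default_tissues() if tissues is None else tissues)
    acq = acquisition or AcquisitionSpec(
        voxel_size=(1.0,) * len(tuple(shape)))
    shape = tuple(int(s) for s in shape)
    if len(shape) != len(acq.voxel_size):
        acq = AcquisitionSpec(acq.tr, acq.te, (1.0,) * len(shape))
    if len(tissues) < 2:
        raise DataFormatError("need at least 2 tissues")

    names = [t.name for t in tissues]
    tumor_idx = next((i for i, nm in enumerate(names)
                      if nm.lower() == "tumor"), None)
    shell_idx = [i for i in range(len(tissues)) if i != tumor_idx]

    rho = _ellipsoid_radius(shape)
    order = np.argsort(rho, axis=None, kind="stable")
    n_brain_default = int((rho <= 1.0).sum())

    if counts is None:
        n_brain = n_brain_default
        n_tumor = int(round(tumor_fraction * n_brain)) \
            if tumor_idx is not None else 0
        shell_counts = {}
        fracs = {0: 0.20, 1: 0.30}  # outer two shells; remainder innermost
        remaining = n_brain - n_tumor
        for k, i in enumerate(shell_idx[:-1]):
            c = int(round(fracs.get(k, 0.25) * remaining))
            shell_counts[i] = c
        shell_counts[shell_idx[-1]] = remaining - sum(
            shell_counts.get(i, 0) for i in shell_idx[:-1])
    else:
        shell_counts = {i: int(counts[names[i]]) for i in shell_idx}
        n_tumor = int(counts.get(names[tumor_idx], 0)) \
            if tumor_idx is not None else 0
        n_brain = sum(shell_counts.values()) + n_tumor
    if n_brain > rho.size:
        raise DataFormatError("requested tissue counts exceed the image size")
    if any(c < 0 for c in shell_counts.values()) or n_tumor < 0:
        raise DataFormatError("tissue counts must be nonnegative")

    labels_flat = np.full(rho.size, OUTSIDE_LABEL, dtype=np.int32)
    brain_sel = order[:n_brain]              # innermost n_brain voxels
    outer_first = brain_sel[::-1]            # walk outside-in
    pos = 0
    for i in shell_idx[:-1]:
        labels_flat[outer_first[pos:pos + shell_counts[i]]] = i
        pos += shell_counts[i]
    core = outer_first[pos:]                 # innermost shell (+ tumor)
    labels_flat[core] = shell_idx[-1]
    if tumor_idx is not None and n_tumor > 0:
        # nearest n_tumor core voxels to an off-center seed point
        center = (np.asarray(shape, dtype=float) - 1.0) / 2.0
        offset = center + 0.18 * np.asarray(shape, dtype=float)
        coords = np.stack(np.unravel_index(core, shape), axis=1).astype(float)
        d2 = ((coords - offset) ** 2).sum(axis=1)
        take = core[np.argsort(d2, kind="stable")[:n_tumor]]
        labels_flat[take] = tumor_idx

    labels = labels_flat.reshape(shape)
    mask = labels != OUTSIDE_LABEL
    signals = np.array([spin_echo_signal(t, acq) for t in tissues])
    data = np.zeros(shape, dtype=float)
    data[mask] = signals[labels[mask]]
    image = GrayImage(data, acq.voxel_size, mask)
    if noise_level > 0:
        image = corrupt(image, noise_model, noise_level, seed)
    return PhantomTruth(image, labels, tissues, acq,
                        {"model": noise_model, "level": float(noise_level),
                         "seed": int(seed)})


def corrupt(image: GrayImage, model: str, level: float, seed: int
            ) -> GrayImage:
    """Seeded noise injection inside the mask; ``level`` 0 is the identity.

    ``gaussian``: additive N(0, level^2). ``rician``: magnitude of the
    signal plus complex Gaussian noise of per-channel std ``level`` (the
    noise model of magnitude MR images). ``salt_pepper``: each in-mask
    voxel is replaced, with probability ``level``, by the masked minimum or
    maximum (coin flip).
    """
    if level < 0:
        raise DomainError("noise level must be >= 0")
    if model not in ("gaussian", "rician", "salt_pepper"):
        raise DataFormatError(f"unknown noise model {model!r}")
    if level == 0:
        return image
    rng = np.random.default_rng(seed)
    vals = image.masked_values().copy()
    if model == "gaussian":
        vals = vals + rng.normal(0.0, level, vals.size)
    elif model == "rician":
        vals = np.hypot(vals + rng.normal(0.0, level, vals.size),
                        rng.normal(0.0, level, vals.size))
    else:
        hit = rng.random(vals.size) < level
        lo, hi = vals.min(), vals.max()
        vals[hit] = np.where(rng.random(hit.sum()) < 0.5, lo, hi)
    out = image.intensities.copy()
    if image.mask is None:
        out = vals.reshape(image.shape)
    else:
        out[image.mask] = vals
    return GrayImage(out, image.voxel_size, image.mask)
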